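"""Readers and writers for per-subject paired single-cell matrices.

A study consists of *n* subjects; subject *i* carries two matrices over the
same cells — ``G_i`` (``m_i × p``, e.g. RNA) and ``X_i`` (``m_i × q``, e.g.
ADT surface proteins) — plus a univariate outcome ``y_i`` and optional
per-subject covariates.  Cells are rows and features are columns.  Matrices
arrive either as delimited text (CSV/TSV, header row of feature names) or
as a 10x-style Matrix Market triplet directory (``matrix.mtx`` in
features × cells orientation with ``features.tsv`` / ``barcodes.tsv``
sidecars); a manifest CSV maps ``subject_id`` to the two matrix paths.

Inputs are assumed preprocessed (normalization/QC upstream); missing
values are a hard error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "SubjectOmicPair",
    "StudyData",
    "read_matrix",
    "write_matrix",
    "read_subject_pair",
    "assemble_study",
    "read_study",
    "write_study",
    "write_selection",
    "read_config",
]


class StudyFormatError(ValueError):
    """Raised on malformed or inconsistent study inputs."""


@dataclass
class SubjectOmicPair:
    """Paired cell × feature matrices for one subject (same cells in both)."""

    subject_id: str
    G: np.ndarray
    X: np.ndarray
    feature_names_G: list[str] | None = None
    feature_names_X: list[str] | None = None

    def __post_init__(self):
        self.G = _as_numeric_matrix(self.G, f"G[{self.subject_id}]")
        self.X = _as_numeric_matrix(self.X, f"X[{self.subject_id}]")
        if self.G.shape[0] != self.X.shape[0]:
            raise StudyFormatError(
                f"subject {self.subject_id!r}: G has {self.G.shape[0]} cells "
                f"but X has {self.X.shape[0]} — modalities must share cells"
            )

    @property
    def m(self) -> int:
        """Number of cells."""
        return self.G.shape[0]


@dataclass
class StudyData:
    """A validated n-subject study: paired matrices, outcome, covariates."""

    subjects: list[SubjectOmicPair]
    y: np.ndarray
    outcome_family: str = "gaussian"
    covariates: np.ndarray | None = None
    feature_names_G: list[str] = field(default_factory=list)
    feature_names_X: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.subjects:
            raise StudyFormatError("study has no subjects")
        p = self.subjects[0].G.shape[1]
        q = self.subjects[0].X.shape[1]
        for s in self.subjects:
            if s.G.shape[1] != p or s.X.shape[1] != q:
                raise StudyFormatError(
                    f"subject {s.subject_id!r} has feature counts "
                    f"({s.G.shape[1]}, {s.X.shape[1]}); expected ({p}, {q})"
                )
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        if self.y.size != len(self.subjects):
            raise StudyFormatError(
                f"outcome length {self.y.size} != subject count {len(self.subjects)}"
            )
        if not np.all(np.isfinite(self.y)):
            raise StudyFormatError("outcome contains non-finite values")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != len(self.subjects):
                raise StudyFormatError("covariate rows do not align with subjects")
            if not np.all(np.isfinite(self.covariates)):
                raise StudyFormatError("covariates contain non-finite values")
        if not self.feature_names_G:
            self.feature_names_G = [f"g{k + 1}" for k in range(p)]
        if not self.feature_names_X:
            self.feature_names_X = [f"x{j + 1}" for j in range(q)]
        if self.outcome_family not in ("gaussian", "binomial"):
            raise StudyFormatError(
                f"unknown outcome family {self.outcome_family!r}"
            )

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return self.subjects[0].G.shape[1]

    @property
    def q(self) -> int:
        return self.subjects[0].X.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _as_numeric_matrix(values, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise StudyFormatError(f"{label}: expected a 2-D cells × features matrix")
    if not np.all(np.isfinite(arr)):
        raise StudyFormatError(f"{label}: non-finite or missing values present")
    return arr


# ---------------------------------------------------------------------------
# matrix files


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read one cells × features matrix.

    ``path`` is either a delimited file (``.csv``/``.tsv``, header row of
    feature names, rows = cells) or a 10x-style MTX directory containing
    ``matrix.mtx`` (features × cells), ``features.tsv`` and ``barcodes.tsv``.
    Returns ``(matrix, feature_names)``.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise StudyFormatError(f"{path}: MTX directory lacks matrix.mtx")
        sparse = mmread(mtx)
        dense = np.asarray(sparse.todense() if hasattr(sparse, "todense") else sparse,
                           dtype=float)
        features = _read_lines(path / "features.tsv")
        if len(features) != dense.shape[0]:
            raise StudyFormatError(
                f"{path}: {len(features)} feature names for {dense.shape[0]} rows"
            )
        barcodes_path = path / "barcodes.tsv"
        if barcodes_path.exists():
            barcodes = _read_lines(barcodes_path)
            if len(barcodes) != dense.shape[1]:
                raise StudyFormatError(
                    f"{path}: {len(barcodes)} barcodes for {dense.shape[1]} columns"
                )
        return dense.T.copy(), features  # to cells × features
    suffix = path.suffix.lower()
    sep = "\t" if suffix in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except ValueError as exc:
        raise StudyFormatError(f"{path}: cannot parse delimited matrix: {exc}")
    if df.isna().any().any():
        raise StudyFormatError(f"{path}: missing values are not allowed")
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise StudyFormatError(f"{path}: non-numeric cell values: {exc}")
    return mat, [str(c) for c in df.columns]


def write_matrix(matrix: np.ndarray, path: str | Path,
                 feature_names: Sequence[str] | None = None,
                 fmt: str = "csv") -> Path:
    """Write a cells × features matrix as CSV or a 10x-style MTX directory."""
    matrix = np.asarray(matrix)
    path = Path(path)
    names = list(feature_names) if feature_names is not None else [
        f"f{k + 1}" for k in range(matrix.shape[1])
    ]
    if fmt == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(matrix, columns=names).to_csv(path, index=False)
    elif fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = coo_matrix(matrix.T)  # features × cells on disk
        mmwrite(path / "matrix.mtx", sparse)
        (path / "features.tsv").write_text("\n".join(names) + "\n")
        (path / "barcodes.tsv").write_text(
            "\n".join(f"cell{i + 1}" for i in range(matrix.shape[0])) + "\n"
        )
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    return path


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise StudyFormatError(f"missing sidecar file {path}")
    return [ln.split("\t")[0] for ln in path.read_text().splitlines() if ln.strip()]


def read_subject_pair(path_G: str | Path, path_X: str | Path,
                      subject_id: str = "") -> SubjectOmicPair:
    """Read one subject's paired matrices and verify cell alignment."""
    G, names_G = read_matrix(path_G)
    X, names_X = read_matrix(path_X)
    sid = subject_id or Path(path_G).stem
    return SubjectOmicPair(subject_id=sid, G=G, X=X,
                           feature_names_G=names_G, feature_names_X=names_X)


# ---------------------------------------------------------------------------
# study assembly


def assemble_study(pairs: Sequence[SubjectOmicPair],
                   outcome: Mapping[str, float] | pd.DataFrame,
                   covariate_columns: Sequence[str] = (),
                   outcome_family: str = "gaussian") -> StudyData:
    """Join subject pairs with the outcome table into a validated study.

    Subjects are ordered by ``subject_id`` so assembly is invariant to input
    order.  ``outcome`` is either a mapping ``subject_id -> y`` or a
    DataFrame with columns ``subject_id``, ``y`` and any covariates.
    """
    if isinstance(outcome, pd.DataFrame):
        if "subject_id" not in outcome.columns or "y" not in outcome.columns:
            raise StudyFormatError("outcome table needs subject_id and y columns")
        table = outcome.set_index(outcome["subject_id"].astype(str))
    else:
        table = pd.DataFrame({"y": pd.Series({str(k): v for k, v in outcome.items()})})
        if covariate_columns:
            raise StudyFormatError("covariate columns require a DataFrame outcome")
    ordered = sorted(pairs, key=lambda s: s.subject_id)
    missing = [s.subject_id for s in ordered if s.subject_id not in table.index]
    if missing:
        raise KeyError(f"subjects missing from outcome table: {missing}")
    y = np.array([float(table.loc[s.subject_id, "y"]) for s in ordered])
    covariates = None
    if covariate_columns:
        absent = [c for c in covariate_columns if c not in table.columns]
        if absent:
            raise StudyFormatError(f"covariate columns not in outcome table: {absent}")
        covariates = np.array(
            [[float(table.loc[s.subject_id, c]) for c in covariate_columns]
             for s in ordered]
        )
    names_G = ordered[0].feature_names_G or []
    names_X = ordered[0].feature_names_X or []
    for s in ordered[1:]:
        if s.feature_names_G and names_G and s.feature_names_G != names_G:
            raise StudyFormatError(
                f"subject {s.subject_id!r}: G feature names differ from first subject"
            )
        if s.feature_names_X and names_X and s.feature_names_X != names_X:
            raise StudyFormatError(
                f"subject {s.subject_id!r}: X feature names differ from first subject"
            )
    return StudyData(subjects=list(ordered), y=y, outcome_family=outcome_family,
                     covariates=covariates, feature_names_G=list(names_G),
                     feature_names_X=list(names_X))


def read_study(manifest_path: str | Path, outcome_path: str | Path,
               covariate_columns: Sequence[str] = (),
               outcome_family: str = "gaussian") -> StudyData:
    """Load a study from a manifest CSV (columns ``subject_id,g_path,x_path``,
    paths relative to the manifest) and an outcome CSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    for col in ("subject_id", "g_path", "x_path"):
        if col not in manifest.columns:
            raise StudyFormatError(f"manifest lacks required column {col!r}")
    base = manifest_path.parent
    pairs = [
        read_subject_pair(base / row.g_path, base / row.x_path,
                          subject_id=str(row.subject_id))
        for row in manifest.itertuples()
    ]
    outcome = pd.read_csv(outcome_path)
    outcome["subject_id"] = outcome["subject_id"].astype(str)
    return assemble_study(pairs, outcome, covariate_columns=covariate_columns,
                          outcome_family=outcome_family)


def write_study(study: StudyData, out_dir: str | Path, fmt: str = "csv",
                truth_G: np.ndarray | None = None,
                truth_X: np.ndarray | None = None) -> Path:
    """Write a study as per-subject matrix files plus manifest and outcome
    tables (and optional ground-truth network labels)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in study.subjects:
        if fmt == "csv":
            g_rel, x_rel = f"{s.subject_id}_G.csv", f"{s.subject_id}_X.csv"
        else:
            g_rel, x_rel = f"{s.subject_id}_G", f"{s.subject_id}_X"
        write_matrix(s.G, out_dir / g_rel, study.feature_names_G, fmt=fmt)
        write_matrix(s.X, out_dir / x_rel, study.feature_names_X, fmt=fmt)
        rows.append({"subject_id": s.subject_id, "g_path": g_rel, "x_path": x_rel})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    outcome = pd.DataFrame({"subject_id": study.subject_ids, "y": study.y})
    if study.covariates is not None:
        for k in range(study.covariates.shape[1]):
            outcome[f"u{k + 1}"] = study.covariates[:, k]
    outcome.to_csv(out_dir / "outcome.csv", index=False)
    for truth, name in ((truth_G, "truth_G.csv"), (truth_X, "truth_X.csv")):
        if truth is not None:
            names = study.feature_names_G if name == "truth_G.csv" else study.feature_names_X
            pd.DataFrame({"feature": names,
                          "index": np.arange(1, len(truth) + 1),
                          "is_network": np.asarray(truth).astype(int)}
                         ).to_csv(out_dir / name, index=False)
    return out_dir


# ---------------------------------------------------------------------------
# results and config


def write_selection(result, out_dir: str | Path,
                    metadata: Mapping | None = None) -> Path:
    """Write the nonzero-support selection tables, one per modality.

    Each table lists feature name, 1-based index, coefficient, and the
    absolute scaled weight (|coef| / max |coef| within the modality, the
    quantity used to color selected features in reports).  A JSON metadata
    file records hyperparameters and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for modality, coefs, names, selected in (
        ("X", result.fit.beta_X, result.feature_names_X, result.selected_X),
        ("G", result.fit.beta_G, result.feature_names_G, result.selected_G),
    ):
        coefs = np.asarray(coefs, dtype=float)
        scale = np.max(np.abs(coefs)) if np.any(coefs) else 1.0
        sel = np.asarray(sorted(selected), dtype=int)
        pd.DataFrame({
            "feature": [names[j] for j in sel],
            "index": sel + 1,
            "coefficient": coefs[sel],
            "abs_scaled_weight": np.abs(coefs[sel]) / scale,
        }).to_csv(out_dir / f"selection_{modality}.csv", index=False)
    meta = dict(metadata or {})
    meta.setdefault("hyperparams", getattr(result, "hyperparams", None))
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return out_dir


def read_config(path: str | Path) -> dict:
    """Read a flat key/value YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise StudyFormatError(f"{path}: config must be a flat mapping")
    return cfg
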