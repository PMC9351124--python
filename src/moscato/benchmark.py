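"""AUC-based competitor selections and confusion-matrix scoring.

The benchmark mirrors the marker-gene convention of standard single-cell
workflows: the continuous outcome is binarized at its median, every cell
inherits its subject's label, and each feature gets a Mann–Whitney AUC
for separating the two label groups over the pooled cells.  Features are
then selected either because the Bonferroni-adjusted p-value of the
AUC = 0.5 null falls below a nominal level, or because the AUC itself
leaves the ``(low, high)`` band (strict inequalities).  Selections are
scored against simulated truth by sensitivity (network features kept)
and specificity (non-network features excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .io_formats import StudyData

__all__ = ["AucResult", "ConfusionMetrics", "binarize_outcome",
           "feature_auc", "modality_auc", "auc_select", "score_selection"]


@dataclass
class AucResult:
    """Per-feature AUC, two-sided p-value (H0: AUC = 0.5), and its
    Bonferroni adjustment."""

    auc: np.ndarray
    p_value: np.ndarray
    p_adjusted: np.ndarray


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def binarize_outcome(y: np.ndarray) -> np.ndarray:
    """Median binarization: strictly below the median → 0, strictly above
    → 1; values equal to the median map to 0 (not greater)."""
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.size < 2:
        raise ValueError("need at least 2 outcome values")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome cannot be binarized")
    return (y > np.median(y)).astype(int)


def _mann_whitney_columns(values: np.ndarray, labels: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected Mann–Whitney over columns.

    Returns (AUC, two-sided normal-approximation p-value) per column,
    with ties credited 0.5 via midranks.
    """
    n = values.shape[0]
    n1 = int(labels.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(values, axis=0)
    r1 = ranks[labels == 1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    auc = u1 / (n0 * n1)
    # tie correction per column: sum over tie groups of (t^3 - t)
    sorted_vals = np.sort(values, axis=0)
    ties = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(sorted_vals[:, j], return_counts=True)
        ties[j] = np.sum(counts.astype(float) ** 3 - counts)
    var_u = n0 * n1 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - n0 * n1 / 2.0) / np.sqrt(var_u)
    z = np.where(var_u > 0, z, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return auc, np.minimum(p, 1.0)


def feature_auc(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and two-sided p-value for one feature (ties credited 0.5)."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels, dtype=int).reshape(-1)
    auc, p = _mann_whitney_columns(values, labels)
    return float(auc[0]), float(p[0])


def modality_auc(values: np.ndarray, labels: np.ndarray) -> AucResult:
    """AUC result for every column of a units × features matrix."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int).reshape(-1)
    auc, p = _mann_whitney_columns(values, labels)
    return AucResult(auc=auc, p_value=p,
                     p_adjusted=np.minimum(p * values.shape[1], 1.0))


def _pooled_values(study: StudyData, modality: str, labels: np.ndarray,
                   unit: str) -> tuple[np.ndarray, np.ndarray]:
    mats = [getattr(s, modality) for s in study.subjects]
    if unit == "cell":
        values = np.concatenate(mats, axis=0)
        cell_labels = np.concatenate(
            [np.full(m.shape[0], labels[i]) for i, m in enumerate(mats)]
        )
        return values, cell_labels
    if unit == "subject":
        values = np.stack([m.mean(axis=0) for m in mats], axis=0)
        return values, labels
    raise ValueError(f"unknown AUC unit {unit!r}")


def auc_select(study: StudyData, criterion: str = "pvalue",
               alpha: float = 0.05, low: float = 0.3, high: float = 0.7,
               unit: str = "cell") -> dict[str, np.ndarray]:
    """Select features per modality by AUC against the (binarized) outcome.

    ``criterion="pvalue"`` keeps features whose Bonferroni-adjusted
    p-value is below ``alpha``; ``criterion="cutoff"`` keeps features with
    AUC strictly below ``low`` or strictly above ``high``.  Returns 0-based
    index arrays under keys ``"G"`` and ``"X"`` (plus the per-feature
    :class:`AucResult` under ``"auc_G"`` / ``"auc_X"``).
    """
    if criterion not in ("pvalue", "cutoff"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y = study.y
    labels = y.astype(int) if set(np.unique(y)) <= {0.0, 1.0} else binarize_outcome(y)
    out: dict[str, np.ndarray | AucResult] = {}
    for modality in ("G", "X"):
        values, unit_labels = _pooled_values(study, modality, labels, unit)
        res = modality_auc(values, unit_labels)
        if criterion == "pvalue":
            selected = np.flatnonzero(res.p_adjusted < alpha)
        else:
            selected = np.flatnonzero((res.auc < low) | (res.auc > high))
        out[modality] = selected
        out[f"auc_{modality}"] = res
    return out


def score_selection(selected, truth: np.ndarray) -> ConfusionMetrics:
    """Confusion metrics of an index set against a boolean truth vector."""
    truth = np.asarray(truth, dtype=bool).reshape(-1)
    idx = np.asarray(sorted(selected), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= truth.size):
        raise ValueError("selected index out of range of the truth vector")
    mask = np.zeros(truth.size, dtype=bool)
    mask[idx] = True
    return ConfusionMetrics(tp=int(np.sum(mask & truth)),
                            fp=int(np.sum(mask & ~truth)),
                            tn=int(np.sum(~mask & ~truth)),
                            fn=int(np.sum(~mask & truth)))
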