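"""Supervised multimodal single-cell simulator with known network truth.

The generator emulates a CITE-seq-like study: each subject carries a
cells × genes count matrix ``G_i`` and a cells × surface-marker matrix
``X_i`` over the same cells, plus a continuous outcome ``y_i``.  Ground
truth is planted through a block latent structure:

* ``H`` — features in G related to the outcome but to nothing in X;
* ``S`` — features in X related to the outcome but to nothing in G;
* ``G``/``X`` — the *network*: features in G related to features in X
  which in turn relate to the outcome (the target of selection);
* ``G'``/``X'`` — cross-modal features related to each other but not to
  the outcome;
* independent noise features in each modality.

One latent scalar per block per subject is drawn from a zero-mean
multivariate normal whose off-diagonals are nonzero exactly on the edges
above, and every cell additionally receives its own draw over the six
feature blocks.  The cell-level draw is what makes the network
detectable from single cells: features of linked blocks co-fluctuate
across the cells of a subject, and the *strength* of that within-subject
co-expression is subject-specific — a bounded monotone function of the
subject's own linked-block latents.  For the network blocks (G–X, both
tied to y) that strength tracks the outcome, which is precisely the
signal the downstream correlation-tensor regression assumes; for the
decoy pair (G'–X') it varies just as much but independently of the
outcome, and H and S share no cell-level edge at all.

Gaussian latents cannot serve as count means directly, so each cell ×
feature latent ``z`` is mapped through ``z² / sd(z)``, which is
Gamma(shape 1/2, scale 2·sd) distributed — the gene-mean law the
gamma-Poisson count model expects.  The outcome mean passes through the
same transform (see docs/methods.md for why the untransformed latent
would carry no linear supervision).  Counts then follow a Splatter-style
pipeline: feature-level expression outliers, a subject-level dispersion
multiplier (gamma-mixed Poisson), a cell-level log-normal library-size
factor, Poisson sampling, and logistic mean-dependent dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import StudyData, SubjectOmicPair

__all__ = [
    "LatentStructure",
    "SplatterParams",
    "SimulatedStudy",
    "NOISE_LEVELS",
    "build_latent_covariance",
    "simulate_latents",
    "latent_to_gene_mean",
    "simulate_subject_counts",
    "simulate_study",
    "scaled_down_structure",
]

_BLOCKS = ("H", "G", "Gprime", "S", "X", "Xprime")  # + y appended last

#: per-noise-level technical parameters: dropout logistic midpoint x0,
#: gamma-Poisson mixing variance (BCV²), sequencing-depth multiplier, and
#: the shape of the mean-1 subject dispersion multiplier — noisier
#: protocols drop out more entries, carry more overdispersion, sequence
#: shallower, and vary more from subject to subject (batch-like nuisance)
NOISE_LEVELS = {"low": (-2.0, 0.05, 3.0, 20.0, 0.2),
                "moderate": (-0.5, 0.25, 1.5, 8.0, 0.35),
                "high": (2.0, 1.0, 0.4, 0.7, 0.7)}


@dataclass(frozen=True)
class LatentStructure:
    """Block sizes and latent correlations of the planted network.

    Defaults are the study design used throughout: H=15, G=10, G'=15 plus
    1400 noise genes (p=1440) and S=20, X=15, X'=20 plus 1500 noise
    markers (q=1555).  ``rho_link`` ties G–X and G'–X' at the subject
    level; ``rho_y`` ties the direct blocks H and S to the latent
    outcome and ``rho_y_net`` the network blocks G and X (the network is
    the dominant outcome-driving module).  ``coexpr`` is the ceiling of
    the within-subject cell-level co-expression along the linked edges,
    reached by subjects with strong linked-block latents.  ``jitter_sd``
    is the sd of the per-feature deviation around the block latent,
    ``cell_sd`` the sd of the per-cell block draw, and ``loading_sd``
    the log-sd of per-feature cell-component loadings — gene-level
    strengths drawn once per study, so that the same features are
    strongly networked in every subject (hub-like persistence);
    ``sigma_y`` is the observation noise of the outcome.
    """

    n_h: int = 15
    n_g: int = 10
    n_gprime: int = 15
    n_noise_g: int = 1400
    n_s: int = 20
    n_x: int = 15
    n_xprime: int = 20
    n_noise_x: int = 1500
    rho_link: float = 0.6
    rho_y: float = 0.2
    rho_y_net: float = 0.85
    coexpr: float = 0.95
    jitter_sd: float = 0.3
    cell_sd: float = 1.0
    loading_sd: float = 0.4
    sigma_y: float = 0.2
    outcome_transform: str = "squared"  # or "identity"

    @property
    def p(self) -> int:
        return self.n_h + self.n_g + self.n_gprime + self.n_noise_g

    @property
    def q(self) -> int:
        return self.n_s + self.n_x + self.n_xprime + self.n_noise_x

    def block_sizes_g(self) -> dict[str, int]:
        return {"H": self.n_h, "G": self.n_g, "Gprime": self.n_gprime,
                "noise": self.n_noise_g}

    def block_sizes_x(self) -> dict[str, int]:
        return {"S": self.n_s, "X": self.n_x, "Xprime": self.n_xprime,
                "noise": self.n_noise_x}


def scaled_down_structure(noise_factor: int = 5, **overrides) -> LatentStructure:
    """Desk-scale variant: noise feature counts divided by ``noise_factor``,
    network blocks unchanged."""
    return LatentStructure(n_noise_g=1400 // noise_factor,
                           n_noise_x=1500 // noise_factor, **overrides)


@dataclass(frozen=True)
class SplatterParams:
    """Count-model parameters (Splatter-style gamma-Poisson pipeline).

    ``mean_cells`` — Poisson mean of the per-subject cell count;
    ``noise_gamma`` — (shape, scale) of independent noise-feature means;
    ``mean_scale`` — overall sequencing-depth multiplier applied to all
    rates (sets the typical counts-per-cell scale);
    ``lib_sigma`` — sd of the log-normal per-cell library factor;
    ``outlier_prob`` / ``outlier_loc`` / ``outlier_scale`` — expression
    outlier flags replacing a feature's mean by median × LogNormal(loc,
    scale); ``dispersion`` — variance of the gamma mixing at subject
    multiplier 1; ``disp_subject_shape`` — shape of the mean-1 gamma
    subject multiplier; ``dropout_mid`` (x0) / ``dropout_shape`` (k) —
    logistic dropout on log mean.
    """

    mean_cells: float = 500.0
    noise_gamma: tuple[float, float] = (0.6, 2.0)
    mean_scale: float = 3.0
    lib_sigma: float = 0.2
    outlier_prob: float = 0.05
    outlier_loc: float = 1.0
    outlier_scale: float = 0.5
    dispersion: float = 0.05
    disp_subject_shape: float = 20.0
    dropout_mid: float = -1.0
    dropout_shape: float = 1.0
    noise_level: str = "low"

    def __post_init__(self):
        if self.mean_cells <= 0 or self.lib_sigma <= 0:
            raise ValueError("scales must be positive")
        if not 0 <= self.outlier_prob <= 1:
            raise ValueError("outlier_prob must be in [0, 1]")

    @classmethod
    def for_setting(cls, cells: float, noise: str, **overrides) -> "SplatterParams":
        """Named simulation setting: average cells per subject in
        {250, 500, 1000} × technical noise in {low, moderate, high}."""
        if noise not in NOISE_LEVELS:
            raise ValueError(f"noise level must be one of {sorted(NOISE_LEVELS)}")
        mid, bcv2, depth, subj_shape, lib = NOISE_LEVELS[noise]
        overrides.setdefault("dropout_mid", mid)
        overrides.setdefault("dispersion", bcv2)
        overrides.setdefault("mean_scale", depth)
        overrides.setdefault("disp_subject_shape", subj_shape)
        overrides.setdefault("lib_sigma", lib)
        return cls(mean_cells=float(cells), noise_level=noise, **overrides)


@dataclass
class SimulatedStudy:
    """A generated study plus its latent values and truth labels."""

    study: StudyData
    truth_G: np.ndarray
    truth_X: np.ndarray
    latents: dict[str, np.ndarray]
    seed: int | None = None


# ---------------------------------------------------------------------------
# latent layer


def build_latent_covariance(ls: LatentStructure) -> np.ndarray:
    """Covariance of the block latents ``(H, G, G', S, X, X', y)``.

    Off-diagonals are nonzero exactly on the planted edges: G–X and G'–X'
    at ``rho_link``; H–y and S–y at ``rho_y``; G–y and X–y at
    ``rho_y_net``.  Everything else (H–S, H–X, G'–y, X'–y, ...) is zero.
    Positive definiteness is verified numerically.
    """
    names = list(_BLOCKS) + ["y"]
    k = len(names)
    cov = np.eye(k)
    idx = {name: i for i, name in enumerate(names)}

    def set_edge(a, b, value):
        cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = value

    set_edge("G", "X", ls.rho_link)
    set_edge("Gprime", "Xprime", ls.rho_link)
    for block in ("H", "S"):
        set_edge(block, "y", ls.rho_y)
    for block in ("G", "X"):
        set_edge(block, "y", ls.rho_y_net)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 1e-10:
        raise ValueError(
            f"latent covariance is not positive definite for "
            f"rho_link={ls.rho_link}, rho_y={ls.rho_y}, "
            f"rho_y_net={ls.rho_y_net} "
            f"(smallest eigenvalue {eigvals.min():.3g})"
        )
    return cov


def simulate_latents(ls: LatentStructure, n: int,
                     seed: int | np.random.Generator | None = None
                     ) -> dict[str, np.ndarray]:
    """n subject draws of the 7 block latents; returns a name → (n,) map."""
    if n < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    cov = build_latent_covariance(ls)
    draws = rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n,
                                    method="cholesky")
    names = list(_BLOCKS) + ["y"]
    return {name: draws[:, i] for i, name in enumerate(names)}


def latent_to_gene_mean(z: np.ndarray | float,
                        sd: np.ndarray | float) -> np.ndarray | float:
    """Gamma transform ``z² / sd``: for ``z ~ N(0, sd²)`` the output is
    Gamma(shape 1/2, scale 2·sd) distributed, the form the count model
    expects for gene means.  ``sd`` may be a scalar or per-feature array."""
    if np.any(np.asarray(sd) <= 0):
        raise ValueError(f"sd must be positive, got {sd}")
    return np.square(z) / sd


# ---------------------------------------------------------------------------
# count layer


def simulate_subject_counts(gene_means: np.ndarray, m: int, sp: SplatterParams,
                            seed: int | np.random.Generator | None = None
                            ) -> np.ndarray:
    """One subject's ``m × n_features`` count matrix.

    ``gene_means`` is either one mean per feature (shared by all cells)
    or a full ``m × n_features`` rate matrix.  Pipeline: (a) expression
    outliers — with probability ``outlier_prob`` a feature's mean is
    replaced by median(means) × LogNormal factor; (b) one mean-1 gamma
    subject multiplier scales the gamma-Poisson mixing variance; (c) a
    log-normal library factor per cell scales all of that cell's rates;
    (d) Poisson counts on the gamma-mixed rates; (e) logistic dropout:
    a count is zeroed with probability ``1 / (1 + exp(k (log(rate) -
    x0)))`` so low-rate entries drop out most often.
    """
    gene_means = np.asarray(gene_means, dtype=float)
    if np.any(gene_means < 0):
        raise ValueError("gene means must be nonnegative")
    if m < 1:
        raise ValueError("need at least one cell")
    if gene_means.ndim == 2 and gene_means.shape[0] != m:
        raise ValueError("2-D gene means must have one row per cell")
    rng = np.random.default_rng(seed)
    means = (np.broadcast_to(gene_means, (m, gene_means.shape[-1])).copy()
             if gene_means.ndim == 1 else gene_means.copy())
    n_feat = means.shape[1]

    # (a) feature-level expression outliers (replace the whole column)
    if sp.outlier_prob > 0 and n_feat:
        outliers = rng.random(n_feat) < sp.outlier_prob
        if outliers.any():
            factors = rng.lognormal(sp.outlier_loc, sp.outlier_scale,
                                    size=int(outliers.sum()))
            means[:, outliers] = np.median(means.mean(axis=0)) * factors[None, :]

    # (b) subject-level dispersion multiplier (mean 1)
    disp_mult = rng.gamma(sp.disp_subject_shape, 1.0 / sp.disp_subject_shape)
    bcv2 = sp.dispersion * disp_mult

    # (c) cell-level library factors
    lib = rng.lognormal(0.0, sp.lib_sigma, size=m)
    rates = lib[:, None] * means

    # (d) gamma-mixed Poisson counts
    if bcv2 > 0:
        shape = 1.0 / bcv2
        mixing = rng.gamma(shape, bcv2, size=rates.shape)
        rates_mixed = rates * mixing
    else:
        rates_mixed = rates
    counts = rng.poisson(rates_mixed)

    # (e) mean-dependent logistic dropout
    with np.errstate(divide="ignore"):
        logit = sp.dropout_shape * (np.log(rates + 1e-8) - sp.dropout_mid)
    p_drop = 1.0 / (1.0 + np.exp(logit))
    counts[rng.random(counts.shape) < p_drop] = 0
    return counts.astype(np.int64)


def _coexpression_strength(z_a: float, z_b: float, rho_link: float) -> float:
    """Subject-specific co-expression weight in [0, 1]: ``min(t²/4, 1)``
    with ``t`` the standardized mean of the two linked-block latents.
    Linear in ``t²`` over nearly all of its mass (the squared-count
    channel then tracks it almost linearly), clipped so the cell-level
    correlation stays below the ``coexpr`` ceiling.  Subjects with strong
    linked-block latents co-express near the ceiling; subjects near zero
    barely co-express."""
    t = (z_a + z_b) / np.sqrt(2.0 * (1.0 + rho_link))
    return float(min(t * t / 4.0, 1.0))


def _cell_block_covariance(ls: LatentStructure, w_net: float,
                           w_decoy: float) -> np.ndarray:
    """Covariance of one subject's per-cell block draws (six feature
    blocks, no y): G–X at ``coexpr · w_net`` and G'–X' at ``coexpr ·
    w_decoy``, scaled by ``cell_sd``²."""
    cov = np.eye(len(_BLOCKS))
    idx = {name: i for i, name in enumerate(_BLOCKS)}
    cov[idx["G"], idx["X"]] = cov[idx["X"], idx["G"]] = ls.coexpr * w_net
    cov[idx["Gprime"], idx["Xprime"]] = cov[idx["Xprime"], idx["Gprime"]] = \
        ls.coexpr * w_decoy
    return ls.cell_sd**2 * cov


def _expand_block_rates(z_block: float, cell_component: np.ndarray,
                        loadings: np.ndarray, ls: LatentStructure,
                        rng: np.random.Generator) -> np.ndarray:
    """cells × size rate block: subject block latent + per-feature jitter
    + loading-weighted per-cell block draw, then the gamma transform.
    ``loadings`` are the study-level per-feature strengths."""
    size = loadings.size
    jitter = rng.normal(0.0, ls.jitter_sd, size=size)
    z = z_block + jitter[None, :] + cell_component[:, None] * loadings[None, :]
    sd = np.sqrt(1.0 + ls.jitter_sd**2 + (loadings * ls.cell_sd) ** 2)
    return latent_to_gene_mean(z, sd[None, :])


def simulate_study(ls: LatentStructure | None = None,
                   sp: SplatterParams | None = None,
                   n: int = 100,
                   seed: int | None = None) -> SimulatedStudy:
    """Simulate a full study of ``n`` subjects.

    G columns are ordered (H, G, G', noise) and X columns (S, X, X',
    noise); ``truth_G`` / ``truth_X`` mark the network blocks.  Per-subject
    cell counts are Poisson around ``sp.mean_cells`` (floored at 3 so a
    correlation is always estimable), and the observed outcome is normal
    around the (gamma-transformed) outcome latent.
    """
    ls = ls or LatentStructure()
    sp = sp or SplatterParams()
    if n < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    latents = simulate_latents(ls, n, rng)

    if ls.outcome_transform == "squared":
        y_mean = latent_to_gene_mean(latents["y"], 1.0)
    elif ls.outcome_transform == "identity":
        y_mean = latents["y"]
    else:
        raise ValueError(f"unknown outcome_transform {ls.outcome_transform!r}")
    y = y_mean + rng.normal(0.0, ls.sigma_y, size=n)

    shape_noise, scale_noise = sp.noise_gamma
    subjects = []
    m_all = np.maximum(rng.poisson(sp.mean_cells, size=n), 3)
    # per-feature cell-component loadings: study-level gene identities
    block_sizes = {"H": ls.n_h, "G": ls.n_g, "Gprime": ls.n_gprime,
                   "S": ls.n_s, "X": ls.n_x, "Xprime": ls.n_xprime}
    loadings = {name: rng.lognormal(0.0, ls.loading_sd, size=size)
                for name, size in block_sizes.items()}
    w_net = np.empty(n)
    w_decoy = np.empty(n)
    for i in range(n):
        m = int(m_all[i])
        w_net[i] = _coexpression_strength(latents["G"][i], latents["X"][i],
                                          ls.rho_link)
        w_decoy[i] = _coexpression_strength(latents["Gprime"][i],
                                            latents["Xprime"][i], ls.rho_link)
        cell_cov = _cell_block_covariance(ls, w_net[i], w_decoy[i])
        cells = rng.multivariate_normal(np.zeros(len(_BLOCKS)), cell_cov,
                                        size=m, method="cholesky")
        cell_of = {name: cells[:, k] for k, name in enumerate(_BLOCKS)}
        rate_parts_g = [
            _expand_block_rates(latents["H"][i], cell_of["H"],
                                loadings["H"], ls, rng),
            _expand_block_rates(latents["G"][i], cell_of["G"],
                                loadings["G"], ls, rng),
            _expand_block_rates(latents["Gprime"][i], cell_of["Gprime"],
                                loadings["Gprime"], ls, rng),
            np.broadcast_to(rng.gamma(shape_noise, scale_noise,
                                      size=ls.n_noise_g), (m, ls.n_noise_g)),
        ]
        rate_parts_x = [
            _expand_block_rates(latents["S"][i], cell_of["S"],
                                loadings["S"], ls, rng),
            _expand_block_rates(latents["X"][i], cell_of["X"],
                                loadings["X"], ls, rng),
            _expand_block_rates(latents["Xprime"][i], cell_of["Xprime"],
                                loadings["Xprime"], ls, rng),
            np.broadcast_to(rng.gamma(shape_noise, scale_noise,
                                      size=ls.n_noise_x), (m, ls.n_noise_x)),
        ]
        # one combined pass so outliers/library/dispersion act jointly,
        # features split back by modality afterwards
        all_rates = sp.mean_scale * np.concatenate(rate_parts_g + rate_parts_x,
                                                   axis=1)
        counts = simulate_subject_counts(all_rates, m, sp, rng)
        subjects.append(SubjectOmicPair(
            subject_id=f"S{i + 1:04d}",
            G=counts[:, :ls.p], X=counts[:, ls.p:],
        ))

    names_g = [f"gene_{k + 1:05d}" for k in range(ls.p)]
    names_x = [f"adt_{j + 1:05d}" for j in range(ls.q)]
    study = StudyData(subjects=subjects, y=y, outcome_family="gaussian",
                      feature_names_G=names_g, feature_names_X=names_x)
    truth_G = np.zeros(ls.p, dtype=bool)
    truth_G[ls.n_h:ls.n_h + ls.n_g] = True
    truth_X = np.zeros(ls.q, dtype=bool)
    truth_X[ls.n_s:ls.n_s + ls.n_x] = True
    return SimulatedStudy(study=study, truth_G=truth_G, truth_X=truth_X,
                          latents={**latents, "y_mean": y_mean,
                                   "coexpr_net": w_net,
                                   "coexpr_decoy": w_decoy}, seed=seed)
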