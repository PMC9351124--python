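"""Stability-based hyperparameter tuning (an extension of StARS).

Accuracy-driven tuning (cross-validation, BIC) tends toward dense,
irreproducible solutions in high dimensions.  The stability approach
instead starts from the sparsest solution and relaxes sparsity until the
selections become unstable across subject subsamples.  For each candidate
support cap, selection is repeated on R subsamples of c subjects for every
candidate L1 weight alpha; per-feature selection frequencies theta_j give
the instability

    D = mean_j 2 * theta_j * (1 - theta_j),

which is 0 when every subsample selects the identical set and at most 0.5.
The cap is grown while the best-alpha instability stays below the
threshold phi; the tuned value is the largest cap still under phi
(prioritizing type-II error: tuned caps are expected to exceed the true
network size).  The two dimensions are tuned one at a time: first
(alpha_X, max_X) with the G dimension held wide open (alpha_G = 0.5,
max_G = floor(p/2)), then (alpha_G, max_G) at the tuned X values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb, floor

import numpy as np

from .correlation import build_tensor_set
from .io_formats import StudyData
from .regression import MoscatoFitError, Rank1TensorGLM
from .select import MoscatoHyperParams

__all__ = ["TuningConfig", "InstabilityEstimate", "subsample_plans",
           "estimate_instability", "tune_dimension", "tune_all",
           "StabilityTuner"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TuningConfig:
    """Tuning-loop settings.

    ``grid_alpha`` — candidate L1 weights; ``phi`` — instability threshold;
    ``n_subsamples`` (R) and ``subsample_size`` (c) — subsampling scheme
    over subjects; ``max_init_X`` / ``max_init_G`` — starting caps;
    ``max_step`` — cap increment per round.
    """

    grid_alpha: tuple[float, ...] = (0.2, 0.5, 0.7)
    phi: float = 0.02
    n_subsamples: int = 50
    subsample_size: int = 50
    max_init_X: int = 5
    max_init_G: int = 5
    max_step: int = 5
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.phi <= 0.5:
            raise ValueError(f"phi must be in (0, 0.5], got {self.phi}")
        if any(not 0 <= a <= 1 for a in self.grid_alpha):
            raise ValueError("grid_alpha values must lie in [0, 1]")
        if self.n_subsamples < 2:
            raise ValueError("need at least 2 subsamples")


@dataclass
class InstabilityEstimate:
    """Per-feature selection frequencies and their mean instability."""

    theta: np.ndarray
    instability: float


def subsample_plans(n: int, c: int, R: int,
                    seed: int | None = None) -> list[np.ndarray]:
    """R subject index subsets of size c, drawn without replacement within
    each subset.

    With ``c = n - 1`` and ``R >= n`` the scheme becomes leave-one-out:
    the n distinct subsets are each used at least once (cycled in order of
    the left-out subject).  Duplicate subsets are permitted (with a
    warning) when R exceeds the number of distinct subsets.
    """
    if not 1 <= c < n:
        raise ValueError(f"subsample size c={c} must satisfy 1 <= c < n={n}")
    rng = np.random.default_rng(seed)
    if c == n - 1:
        loo = [np.array([i for i in range(n) if i != left]) for left in range(n)]
        return [loo[r % n] for r in range(R)]
    if comb(n, c) < R:
        logger.warning("only %d distinct subsets of size %d exist for n=%d; "
                       "duplicates will occur across %d subsamples",
                       comb(n, c), c, n, R)
    return [np.sort(rng.choice(n, size=c, replace=False)) for _ in range(R)]


def estimate_instability(selection_sets, dimension_size: int) -> InstabilityEstimate:
    """StARS instability of a collection of selected index sets:
    ``mean_j 2 theta_j (1 - theta_j)`` with theta_j the selection frequency
    of feature j over the sets (never-selected features contribute 0)."""
    sets = list(selection_sets)
    if len(sets) < 2:
        raise ValueError("at least 2 selection sets are required")
    counts = np.zeros(dimension_size)
    for s in sets:
        idx = np.asarray(sorted(s), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= dimension_size):
            raise ValueError("selection index out of range")
        counts[idx] += 1
    theta = counts / len(sets)
    return InstabilityEstimate(theta=theta,
                               instability=float(np.mean(2 * theta * (1 - theta))))


def _selection_for(Z, y, U, family, alpha_X, alpha_G, max_X, max_G, dim, seed):
    """One subsample fit; returns the tuned dimension's selected index set.

    Subsample fits run a single screen-initialized block alternation
    (the selection step of the full algorithm) rather than iterating to
    convergence: thousands of them run per tuning pass, the support is
    determined in the first alternation, and further local search only
    adds optimizer noise to the very quantity — selection consistency —
    that the instability estimate measures."""
    model = Rank1TensorGLM(family=family, alpha_X=alpha_X, alpha_G=alpha_G,
                           max_X=max_X, max_G=max_G, init="spectral",
                           max_iter=1, n_alphas=30, random_state=seed)
    try:
        model.fit(Z, y, U)
    except MoscatoFitError as exc:
        logger.warning("subsample fit failed (%s); counting an empty selection", exc)
        return frozenset()
    beta = model.beta_X_ if dim == "X" else model.beta_G_
    return frozenset(np.flatnonzero(beta != 0).tolist())


@dataclass
class _DimensionTrail:
    records: list[dict] = field(default_factory=list)
    warning: str | None = None


def tune_dimension(Z: np.ndarray, y: np.ndarray, U, family: str, dim: str,
                   fixed_other: tuple[float, int], cfg: TuningConfig,
                   plans: list[np.ndarray] | None = None
                   ) -> tuple[int, float, _DimensionTrail]:
    """Grow the support cap of one dimension until the phi instability is
    hit; returns ``(max, alpha, trail)`` — the largest cap whose best-alpha
    instability stayed below phi, with that alpha (ties broken toward the
    smallest alpha, which leans on the stabilizing L2 term)."""
    n, q, p = Z.shape
    dim_size = q if dim == "X" else p
    cap_limit = dim_size
    alpha_other, max_other = fixed_other
    if plans is None:
        plans = subsample_plans(n, cfg.subsample_size, cfg.n_subsamples, cfg.seed)
    trail = _DimensionTrail()
    cap = min(cfg.max_init_X if dim == "X" else cfg.max_init_G, cap_limit)
    best: tuple[int, float] | None = None
    while cap <= cap_limit:
        results = {}
        for alpha in cfg.grid_alpha:
            if dim == "X":
                kwargs = dict(alpha_X=alpha, alpha_G=alpha_other,
                              max_X=cap, max_G=min(max_other, p))
            else:
                kwargs = dict(alpha_X=alpha_other, alpha_G=alpha,
                              max_X=min(max_other, q), max_G=cap)
            sets = [
                _selection_for(Z[idx], y[idx],
                               None if U is None else U[idx],
                               family, dim=dim, seed=cfg.seed, **kwargs)
                for idx in plans
            ]
            results[alpha] = estimate_instability(sets, dim_size).instability
        best_alpha = min(cfg.grid_alpha,
                         key=lambda a: (results[a], a))  # tie -> smallest alpha
        best_inst = results[best_alpha]
        trail.records.append({"dim": dim, "cap": cap, "alpha": best_alpha,
                              "instability": best_inst,
                              "all_alphas": dict(results)})
        if best_inst >= cfg.phi:
            break
        best = (cap, best_alpha)
        cap += cfg.max_step
    if best is None:
        trail.warning = (
            f"initial cap {cfg.max_init_X if dim == 'X' else cfg.max_init_G} "
            f"already unstable for dimension {dim}; returning it unchanged"
        )
        logger.warning(trail.warning)
        init = trail.records[0]["cap"]
        fallback_alpha = min(
            cfg.grid_alpha,
            key=lambda a: (trail.records[0]["all_alphas"][a], a),
        )
        return init, fallback_alpha, trail
    return best[0], best[1], trail


def tune_all(study: StudyData, cfg: TuningConfig) -> MoscatoHyperParams:
    """Tune all four hyperparameters (functional wrapper over
    :class:`StabilityTuner`)."""
    return StabilityTuner(cfg).fit(study).hyperparams_


class StabilityTuner:
    """Two-pass stability tuner.

    ``fit`` accepts a :class:`StudyData` (or a precomputed tensor set via
    ``fit_tensors``).  The correlation tensor is built once; subsampling
    subsets subjects of the prebuilt tensor.  Attributes after fitting:
    ``alpha_X_``, ``max_X_``, ``alpha_G_``, ``max_G_``, ``hyperparams_``,
    ``trail_`` (per-cap instability records for both passes).
    """

    def __init__(self, config: TuningConfig | None = None, **overrides):
        if config is None:
            config = TuningConfig(**overrides)
        elif overrides:
            raise ValueError("pass either a TuningConfig or keyword overrides")
        self.config = config

    def fit(self, study: StudyData):
        tensors = build_tensor_set(study)
        return self.fit_tensors(tensors.Z, study.y, U=study.covariates,
                                family=study.outcome_family)

    def fit_tensors(self, Z: np.ndarray, y: np.ndarray,
                    U: np.ndarray | None = None, family: str = "gaussian"):
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        n, q, p = Z.shape
        cfg = self.config
        if cfg.subsample_size >= n:
            raise ValueError(
                f"subsample size {cfg.subsample_size} must be below n={n}"
            )
        plans = subsample_plans(n, cfg.subsample_size, cfg.n_subsamples, cfg.seed)
        # pass 1: X dimension, G held wide open
        max_X, alpha_X, trail_X = tune_dimension(
            Z, y, U, family, "X", fixed_other=(0.5, max(1, floor(p / 2))),
            cfg=cfg, plans=plans)
        # pass 2: G dimension at the tuned X values
        max_G, alpha_G, trail_G = tune_dimension(
            Z, y, U, family, "G", fixed_other=(alpha_X, max_X),
            cfg=cfg, plans=plans)
        self.alpha_X_, self.max_X_ = alpha_X, max_X
        self.alpha_G_, self.max_G_ = alpha_G, max_G
        self.trail_ = list(itertools.chain(trail_X.records, trail_G.records))
        self.warnings_ = [w for w in (trail_X.warning, trail_G.warning) if w]
        self.hyperparams_ = MoscatoHyperParams(alpha_X=alpha_X, alpha_G=alpha_G,
                                               max_X=max_X, max_G=max_G)
        return self
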