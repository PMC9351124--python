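"""Rank-1 tensor generalized linear model fitted by block relaxation with
per-dimension elastic-net constraints.

The model for subject *i* with predictor matrix ``Z_i ∈ R^{q×p}`` (a
2-D tensor), outcome ``y_i`` and optional covariates ``u_i`` is

    g(mu_i) = beta_0 + lambda' u_i + <beta_X ∘ beta_G, Z_i>
            = beta_0 + lambda' u_i + beta_X' Z_i beta_G,

with canonical link ``g`` (identity for gaussian, logit for binomial).
Estimation alternates between the two coefficient blocks: holding
``beta_G`` fixed, the model is a GLM of ``y`` on the n×q design whose
*i*-th row is ``Z_i beta_G`` (and symmetrically for ``beta_G``).  Each
block is fitted with an elastic-net penalty whose magnitude is not a free
hyperparameter: the penalty path is walked from strong to weak and the
largest-support solution with at most ``max_nonzero`` nonzero
coefficients is kept, which reparameterizes the penalty weight as a cap
on the support size.

The factorization ``beta_X ∘ beta_G`` is scale non-identifiable
(``(τ β_X, β_G/τ)`` gives the same predictor); on exit ``beta_G`` is
normalized to unit L2 norm with the magnitude absorbed into ``beta_X``.
The block iteration may converge to a local optimum; seed-controlled
random restarts are used when a block degenerates to all zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, enet_path

__all__ = [
    "ElasticNetSpec",
    "TensorFit",
    "Rank1TensorGLM",
    "fit_rank1_tensor_glm",
    "linear_predictor",
    "MoscatoFitError",
]

# a pure-L2 path never yields exact zeros, so the support-cap rule needs
# at least a sliver of L1
_MIN_L1_RATIO = 0.01


class MoscatoFitError(RuntimeError):
    """Block relaxation failed (degenerate blocks or non-finite objective)."""


@dataclass(frozen=True)
class ElasticNetSpec:
    """Per-dimension constraint: L1 weight ``alpha`` in [0, 1] and a cap
    ``max_nonzero`` on the support size."""

    alpha: float
    max_nonzero: int

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.max_nonzero < 1:
            raise ValueError(f"max_nonzero must be >= 1, got {self.max_nonzero}")


@dataclass
class TensorFit:
    """Fitted rank-1 tensor GLM coefficients and convergence record."""

    beta0: float
    covariate_coefs: np.ndarray
    beta_X: np.ndarray
    beta_G: np.ndarray
    family: str
    trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def linear_predictor(fit: TensorFit, Z: np.ndarray,
                     u: np.ndarray | None = None) -> np.ndarray:
    """``beta0 + lambda'u + beta_X' Z beta_G`` for one ``q×p`` matrix or a
    stacked ``(n, q, p)`` array."""
    Z = np.asarray(Z, dtype=float)
    single = Z.ndim == 2
    if single:
        Z = Z[None]
    if Z.shape[1] != fit.beta_X.size or Z.shape[2] != fit.beta_G.size:
        raise ValueError(
            f"Z of shape {Z.shape[1:]} incompatible with coefficient "
            f"lengths ({fit.beta_X.size}, {fit.beta_G.size})"
        )
    eta = fit.beta0 + np.einsum("nqp,q,p->n", Z, fit.beta_X, fit.beta_G)
    if u is not None:
        u = np.atleast_2d(np.asarray(u, dtype=float))
        if u.shape[-1] != fit.covariate_coefs.size:
            raise ValueError("covariate vector length mismatch")
        eta = eta + u @ fit.covariate_coefs
    return float(eta[0]) if single else eta


def _deviance(y: np.ndarray, eta: np.ndarray, family: str) -> float:
    if family == "gaussian":
        return float(np.sum((y - eta) ** 2))
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _pick_path_solution(coefs: np.ndarray, cap: int) -> np.ndarray:
    """From path solutions (columns ordered strong → weak penalty), return
    the largest-support solution with support <= cap; weakest penalty wins
    ties.  If even the strongest penalty is too dense, the strongest
    solution is truncated to its cap largest magnitudes."""
    nnz = np.count_nonzero(coefs, axis=0)
    ok = np.flatnonzero((nnz <= cap) & (nnz > 0))
    if ok.size:
        best = nnz[ok].max()
        idx = ok[np.flatnonzero(nnz[ok] == best)[-1]]
        return coefs[:, idx].copy()
    # the support jumped from empty past the cap within one path step
    # (or started above it): truncate the first over-cap solution
    over = np.flatnonzero(nnz > cap)
    if not over.size:
        return np.zeros(coefs.shape[0])
    coef = coefs[:, over[0]].copy()
    keep = np.argsort(np.abs(coef))[-cap:]
    mask = np.zeros_like(coef, dtype=bool)
    mask[keep] = True
    coef[~mask] = 0.0
    return coef


def _spectral_init(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Supervised spectral start for the G block: the top right singular
    vector of the q×p matrix of entrywise correlations between the
    predictor tensors and the outcome, hard-thresholded at 3/sqrt(n)
    before the SVD.  The truncation removes the dense sea of
    chance-level correlations so that a coherent outcome-linked rank-1
    block dominates the leading direction even at small n."""
    ys = y - y.mean()
    norm_y = np.linalg.norm(ys)
    n, _, p = Z.shape
    if norm_y == 0:
        return np.full(p, 1.0 / np.sqrt(p))
    ys /= norm_y
    Zc = Z - Z.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Zc, axis=0)
    norms[norms == 0] = 1.0
    R = np.einsum("nqp,n->qp", Zc / norms, ys)
    truncated = np.where(np.abs(R) >= 3.0 / np.sqrt(n), R, 0.0)
    if np.any(truncated):
        R = truncated
    _, _, vt = np.linalg.svd(R, full_matrices=False)
    v = vt[0]
    if np.sum(v) < 0:  # fix the sign for determinism
        v = -v
    return v


def _gaussian_block(W: np.ndarray, y: np.ndarray, U: np.ndarray | None,
                    spec: ElasticNetSpec, n_alphas: int,
                    path_eps: float, path_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Elastic-net least squares of y on W with unpenalized intercept and
    covariates (handled exactly by Frisch–Waugh residualization)."""
    n = y.size
    Q = np.ones((n, 1)) if U is None else np.column_stack([np.ones(n), U])
    Wr = W - Q @ np.linalg.lstsq(Q, W, rcond=None)[0]
    yr = y - Q @ np.linalg.lstsq(Q, y, rcond=None)[0]
    l1 = max(spec.alpha, _MIN_L1_RATIO)
    alpha_max = float(np.max(np.abs(Wr.T @ yr), initial=0.0)) / (n * l1)
    if not np.isfinite(alpha_max) or alpha_max <= 0:
        coef = np.zeros(W.shape[1])
    else:
        alphas = np.geomspace(alpha_max * 1.0001, alpha_max * path_eps, n_alphas)
        with warnings.catch_warnings():
            # near-tolerance duality gaps at weak penalties are harmless:
            # only the support pattern along the path is consumed
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = enet_path(Wr, yr, l1_ratio=l1, alphas=alphas,
                                    tol=path_tol)
        coef = _pick_path_solution(coefs, spec.max_nonzero)
    gamma = np.linalg.lstsq(Q, y - W @ coef, rcond=None)[0]
    return coef, gamma


def _binomial_block(W: np.ndarray, y: np.ndarray, U: np.ndarray | None,
                    spec: ElasticNetSpec, n_alphas: int,
                    path_eps: float, path_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Elastic-net logistic regression of y on W along a strong→weak
    C-path (saga); covariates ride along in the design and never count
    against the cap."""
    n = y.size
    design = W if U is None else np.column_stack([W, U])
    n_w = W.shape[1]
    l1 = max(spec.alpha, _MIN_L1_RATIO)
    alpha_max = float(np.max(np.abs(W.T @ (y - y.mean())), initial=0.0)) / (n * l1)
    if not np.isfinite(alpha_max) or alpha_max <= 0:
        coef = np.zeros(n_w)
        p0 = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return coef, np.concatenate([[np.log(p0 / (1 - p0))],
                                     np.zeros(0 if U is None else U.shape[1])])
    alphas = np.geomspace(alpha_max, alpha_max * max(path_eps, 1e-4),
                          min(n_alphas, 30))
    model = LogisticRegression(solver="saga", l1_ratio=l1,
                               warm_start=True, max_iter=5000,
                               tol=max(path_tol, 1e-8))
    best = None
    best_nnz = -1
    for alpha in alphas:  # strong → weak
        model.C = 1.0 / (n * alpha)
        model.fit(design, y)
        coef = model.coef_[0, :n_w]
        nnz = int(np.count_nonzero(coef))
        if nnz <= spec.max_nonzero and nnz >= best_nnz:
            best = (coef.copy(), float(model.intercept_[0]),
                    model.coef_[0, n_w:].copy())
            best_nnz = nnz
    if best is None:
        coef = _pick_path_solution(model.coef_[0, :n_w][:, None], spec.max_nonzero)
        best = (coef, float(model.intercept_[0]), model.coef_[0, n_w:].copy())
    coef, intercept, cov = best
    return coef, np.concatenate([[intercept], cov])


class Rank1TensorGLM(BaseEstimator):
    """Rank-1 tensor GLM with per-dimension elastic-net support caps.

    Parameters
    ----------
    family : {"gaussian", "binomial"}
        Outcome family with canonical link.
    alpha_X, alpha_G : float in [0, 1]
        L1 weight of the elastic-net penalty for each dimension.
    max_X, max_G : int or None
        Support-size caps; ``None`` means the full dimension.
    tol : float
        Relative deviance-change convergence tolerance of the outer
        block-relaxation loop.
    max_iter : int
        Maximum outer iterations.
    n_alphas, path_eps, path_tol : int, float, float
        Length, depth and coordinate-descent tolerance of the penalty
        path walked inside each block update (path spans ``alpha_max``
        down to ``alpha_max * path_eps``).  Unpenalized (OLS-limit)
        behavior needs a deep, tight path, e.g. ``path_eps=1e-8,
        path_tol=1e-10``.
    n_restarts : int
        Seed-controlled random re-initializations tried when a block
        degenerates to all zeros.
    init : {"auto", "spectral", "flat"}
        Deterministic start(s): "auto" runs both the supervised spectral
        start and the flat start and keeps the better final fit;
        "spectral"/"flat" run one.
    random_state : int or None
        Seed for restart initializations; the default first initialization
        (uniform ``beta_G``) is deterministic.

    Attributes
    ----------
    intercept_ : float
    covariate_coef_ : ndarray of shape (k,)
    beta_X_ : ndarray of shape (q,)
    beta_G_ : ndarray of shape (p,), unit L2 norm (or all zero)
    deviance_trace_ : list of per-iteration deviances
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, family: str = "gaussian", alpha_X: float = 0.5,
                 alpha_G: float = 0.5, max_X: int | None = None,
                 max_G: int | None = None, tol: float = 1e-6,
                 max_iter: int = 100, n_alphas: int = 50,
                 path_eps: float = 1e-3, path_tol: float = 1e-5,
                 n_restarts: int = 3, init: str = "auto",
                 random_state: int | None = None):
        self.family = family
        self.alpha_X = alpha_X
        self.alpha_G = alpha_G
        self.max_X = max_X
        self.max_G = max_G
        self.tol = tol
        self.max_iter = max_iter
        self.n_alphas = n_alphas
        self.path_eps = path_eps
        self.path_tol = path_tol
        self.n_restarts = n_restarts
        self.init = init
        self.random_state = random_state

    # -- estimation ---------------------------------------------------

    def fit(self, Z: np.ndarray, y: np.ndarray, U: np.ndarray | None = None):
        """Fit on stacked predictor matrices ``Z`` of shape ``(n, q, p)``."""
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 3:
            raise ValueError(f"Z must have shape (n, q, p); got {Z.shape}")
        y = np.asarray(y, dtype=float).reshape(-1)
        n, q, p = Z.shape
        if y.size != n:
            raise ValueError(f"y has length {y.size}; expected {n}")
        if n < 3:
            raise ValueError("at least 3 subjects are required")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binomial family requires a 0/1 outcome")
        if U is not None:
            U = np.atleast_2d(np.asarray(U, dtype=float))
            if U.shape[0] != n:
                raise ValueError("covariate rows do not align with subjects")
        spec_X = ElasticNetSpec(self.alpha_X, min(self.max_X or q, q))
        spec_G = ElasticNetSpec(self.alpha_G, min(self.max_G or p, p))
        block = _gaussian_block if self.family == "gaussian" else _binomial_block

        rng = np.random.default_rng(self.random_state)
        # deterministic starts: a supervised spectral direction (top right
        # singular vector of the entry-outcome correlation matrix) and the
        # flat vector; random restarts only if both degenerate
        if self.init == "auto":
            starts = [_spectral_init(Z, y), np.full(p, 1.0 / np.sqrt(p))]
        elif self.init == "spectral":
            starts = [_spectral_init(Z, y)]
        elif self.init == "flat":
            starts = [np.full(p, 1.0 / np.sqrt(p))]
        else:
            raise ValueError(f"unknown init {self.init!r}")
        n_deterministic = len(starts)
        starts += [None] * self.n_restarts
        result = None
        last_error: Exception | None = None
        for k, start in enumerate(starts):
            if start is None:
                start = rng.standard_normal(p)
                start /= np.linalg.norm(start)
            try:
                candidate = self._relax(Z, y, U, start, spec_X, spec_G, block)
            except MoscatoFitError as exc:
                last_error = exc
                continue
            if result is None or candidate[0] < result[0]:
                result = candidate
            if result is not None and k >= n_deterministic - 1:
                break  # deterministic starts done; randoms are fallbacks only
        if result is None:
            raise MoscatoFitError(
                f"block relaxation failed after {self.n_restarts} restarts"
            ) from last_error

        _, beta_X, beta_G, gamma, trace, converged, n_iter = result
        norm = np.linalg.norm(beta_G)
        if norm > 0:
            beta_G = beta_G / norm
            beta_X = beta_X * norm
        self.intercept_ = float(gamma[0])
        self.covariate_coef_ = np.asarray(gamma[1:], dtype=float)
        self.beta_X_ = beta_X
        self.beta_G_ = beta_G
        self.deviance_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = n_iter
        return self

    def _relax(self, Z, y, U, beta_G, spec_X, spec_G, block):
        trace: list[float] = []
        converged = False
        prev = np.inf
        best = None  # (dev, beta_X, beta_G, gamma)
        seen_supports: dict[tuple, float] = {}
        for it in range(1, self.max_iter + 1):
            W_X = np.einsum("nqp,p->nq", Z, beta_G)
            beta_X, gamma = block(W_X, y, U, spec_X, self.n_alphas,
                                  self.path_eps, self.path_tol)
            if not np.any(beta_X):
                raise MoscatoFitError("X block degenerated to all zeros")
            W_G = np.einsum("nqp,q->np", Z, beta_X)
            beta_G, gamma = block(W_G, y, U, spec_G, self.n_alphas,
                                  self.path_eps, self.path_tol)
            if not np.any(beta_G):
                raise MoscatoFitError("G block degenerated to all zeros")
            eta = gamma[0] + np.einsum("nqp,q,p->n", Z, beta_X, beta_G)
            if U is not None:
                eta = eta + U @ gamma[1:]
            dev = _deviance(y, eta, self.family)
            if not np.isfinite(dev):
                raise MoscatoFitError("non-finite objective during relaxation")
            trace.append(dev)
            if best is None or dev < best[0]:
                best = (dev, beta_X.copy(), beta_G.copy(), gamma.copy())
            if abs(prev - dev) <= self.tol * (abs(dev) + 1e-12):
                converged = True
                break
            # the support pair revisiting an earlier state without further
            # deviance improvement means the iteration entered a selection
            # cycle; the best state seen is the fixed point we report
            signature = (tuple(np.flatnonzero(beta_X)),
                         tuple(np.flatnonzero(beta_G)))
            if signature in seen_supports and \
                    seen_supports[signature] - dev <= self.tol * (abs(dev) + 1e-12):
                converged = True
                break
            seen_supports[signature] = dev
            prev = dev
        best_dev, beta_X, beta_G, gamma = best
        return best_dev, beta_X, beta_G, gamma, trace, converged, it

    # -- prediction ---------------------------------------------------

    def _fit_result(self) -> TensorFit:
        return TensorFit(beta0=self.intercept_,
                         covariate_coefs=self.covariate_coef_,
                         beta_X=self.beta_X_, beta_G=self.beta_G_,
                         family=self.family, trace=self.deviance_trace_,
                         converged=self.converged_, n_iter=self.n_iter_)

    def decision_function(self, Z: np.ndarray,
                          U: np.ndarray | None = None) -> np.ndarray:
        return linear_predictor(self._fit_result(), Z, U)

    def predict(self, Z: np.ndarray, U: np.ndarray | None = None) -> np.ndarray:
        eta = self.decision_function(Z, U)
        if self.family == "binomial":
            return (expit(eta) >= 0.5).astype(float)
        return eta


def fit_rank1_tensor_glm(Z: np.ndarray, y: np.ndarray,
                         U: np.ndarray | None = None,
                         family: str = "gaussian",
                         spec_X: ElasticNetSpec | None = None,
                         spec_G: ElasticNetSpec | None = None,
                         init_seed: int | None = None,
                         **kwargs) -> TensorFit:
    """Functional wrapper around :class:`Rank1TensorGLM` returning a
    :class:`TensorFit`."""
    Z = np.asarray(Z, dtype=float)
    q, p = Z.shape[1], Z.shape[2]
    spec_X = spec_X or ElasticNetSpec(0.5, q)
    spec_G = spec_G or ElasticNetSpec(0.5, p)
    model = Rank1TensorGLM(family=family, alpha_X=spec_X.alpha,
                           alpha_G=spec_G.alpha, max_X=spec_X.max_nonzero,
                           max_G=spec_G.max_nonzero, random_state=init_seed,
                           **kwargs)
    model.fit(Z, y, U)
    return model._fit_result()
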