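"""End-to-end supervised cross-modal feature selection at fixed
hyperparameters: correlation tensor → penalized rank-1 tensor GLM →
nonzero-support feature sets.

The selected network features are exactly the nonzero supports of the two
fitted coefficient vectors: ``{j : beta_X_j != 0}`` in the X modality and
``{k : beta_G_k != 0}`` in the G modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .correlation import CorrelationTensorSet, build_tensor_set
from .io_formats import StudyData
from .regression import ElasticNetSpec, Rank1TensorGLM, TensorFit

__all__ = ["MoscatoHyperParams", "SelectionResult", "MoscatoSelector",
           "moscato_select"]


@dataclass(frozen=True)
class MoscatoHyperParams:
    """The four tuned hyperparameters: L1 weights and support caps."""

    alpha_X: float = 0.5
    alpha_G: float = 0.5
    max_X: int = 5
    max_G: int = 5

    def __post_init__(self):
        ElasticNetSpec(self.alpha_X, self.max_X)
        ElasticNetSpec(self.alpha_G, self.max_G)

    def as_dict(self) -> dict:
        return {"alpha_X": self.alpha_X, "alpha_G": self.alpha_G,
                "max_X": self.max_X, "max_G": self.max_G}


@dataclass
class SelectionResult:
    """Nonzero-support selections (0-based indices) and the underlying fit."""

    selected_X: list[int]
    selected_G: list[int]
    fit: TensorFit
    hyperparams: dict
    feature_names_X: list[str] = field(default_factory=list)
    feature_names_G: list[str] = field(default_factory=list)

    @property
    def selected_X_names(self) -> list[str]:
        return [self.feature_names_X[j] for j in self.selected_X]

    @property
    def selected_G_names(self) -> list[str]:
        return [self.feature_names_G[k] for k in self.selected_G]


class MoscatoSelector(BaseEstimator):
    """Supervised multimodal network feature selector.

    Wraps :class:`~moscato.regression.Rank1TensorGLM` behind a selector
    interface: ``fit`` accepts either a :class:`StudyData` (the correlation
    tensor is built internally) or a precomputed ``(n, q, p)`` tensor with
    an outcome vector.

    Attributes (after fit): ``selected_X_``, ``selected_G_`` (sorted
    0-based index lists), ``support_X_``, ``support_G_`` (boolean masks),
    ``model_`` (the fitted tensor GLM), ``result_``.
    """

    def __init__(self, alpha_X: float = 0.5, alpha_G: float = 0.5,
                 max_X: int = 5, max_G: int = 5, family: str = "gaussian",
                 tol: float = 1e-6, max_iter: int = 100,
                 random_state: int | None = None):
        self.alpha_X = alpha_X
        self.alpha_G = alpha_G
        self.max_X = max_X
        self.max_G = max_G
        self.family = family
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, study, y=None, U=None):
        """Fit from a StudyData / CorrelationTensorSet / raw (n,q,p) array."""
        if isinstance(study, StudyData):
            tensors = build_tensor_set(study)
            Z = tensors.Z
            y = study.y
            U = study.covariates
            family = study.outcome_family
            names_X, names_G = study.feature_names_X, study.feature_names_G
        elif isinstance(study, CorrelationTensorSet):
            Z = study.Z
            family = self.family
            names_X = [f"x{j + 1}" for j in range(Z.shape[1])]
            names_G = [f"g{k + 1}" for k in range(Z.shape[2])]
        else:
            Z = np.asarray(study, dtype=float)
            family = self.family
            names_X = [f"x{j + 1}" for j in range(Z.shape[1])]
            names_G = [f"g{k + 1}" for k in range(Z.shape[2])]
        if y is None:
            raise ValueError("an outcome vector is required")
        n, q, p = Z.shape
        if not (1 <= self.max_X <= q) or not (1 <= self.max_G <= p):
            raise ValueError(
                f"support caps ({self.max_X}, {self.max_G}) must lie within "
                f"dimension sizes ({q}, {p})"
            )
        model = Rank1TensorGLM(family=family, alpha_X=self.alpha_X,
                               alpha_G=self.alpha_G, max_X=self.max_X,
                               max_G=self.max_G, tol=self.tol,
                               max_iter=self.max_iter,
                               random_state=self.random_state)
        model.fit(Z, np.asarray(y, dtype=float), U)
        self.model_ = model
        self.support_X_ = model.beta_X_ != 0
        self.support_G_ = model.beta_G_ != 0
        self.selected_X_ = sorted(np.flatnonzero(self.support_X_).tolist())
        self.selected_G_ = sorted(np.flatnonzero(self.support_G_).tolist())
        self.result_ = SelectionResult(
            selected_X=self.selected_X_, selected_G=self.selected_G_,
            fit=model._fit_result(),
            hyperparams=MoscatoHyperParams(self.alpha_X, self.alpha_G,
                                           self.max_X, self.max_G).as_dict(),
            feature_names_X=list(names_X), feature_names_G=list(names_G))
        return self

    def get_support(self, modality: str, indices: bool = False):
        mask = self.support_X_ if modality == "X" else self.support_G_
        return np.flatnonzero(mask) if indices else mask


def moscato_select(study: StudyData, hp: MoscatoHyperParams,
                   seed: int | None = None) -> SelectionResult:
    """Run the full pipeline at fixed hyperparameters; deterministic given
    ``(study, hp, seed)``."""
    selector = MoscatoSelector(alpha_X=hp.alpha_X, alpha_G=hp.alpha_G,
                               max_X=hp.max_X, max_G=hp.max_G,
                               random_state=seed)
    selector.fit(study)
    return selector.result_
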