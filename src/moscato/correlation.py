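"""Collapse the cellular dimension into per-subject cross-modal
correlation matrices.

Subjects differ in cell count, so their paired matrices cannot be stacked
into one tensor directly.  The first step of the method therefore replaces
each subject's ``(m_i × p, m_i × q)`` pair by the ``q × p`` Pearson
correlation matrix ``Z_i[j, k] = corr(x_ij, g_ik)`` computed over the
``m_i`` cells, giving every subject a predictor tensor of identical shape
with entries standardized to ``[-1, 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import StudyData, SubjectOmicPair

__all__ = ["CorrelationTensorSet", "subject_correlation", "build_tensor_set"]

logger = logging.getLogger(__name__)


class InsufficientCellsError(ValueError):
    """A subject has too few cells for a sample correlation."""


@dataclass
class CorrelationTensorSet:
    """Per-subject ``q × p`` correlation matrices stacked as ``(n, q, p)``."""

    Z: np.ndarray
    subject_ids: list[str]

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def p(self) -> int:
        return self.Z.shape[2]


def _standardize_columns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to unit norm; zero-variance columns become
    all-zero so any correlation against them is 0 by convention."""
    centered = mat - mat.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    degenerate = norms <= 1e-12 * max(1.0, float(np.max(np.abs(mat), initial=0.0)))
    safe = np.where(degenerate, 1.0, norms)
    return centered / safe, degenerate


def subject_correlation(pair: SubjectOmicPair) -> np.ndarray:
    """Pearson correlation matrix ``Z_i[j, k] = corr(X[:, j], G[:, k])``.

    Computed as one matrix product between column-standardized modalities
    (tractable at p ≈ 18k).  Zero-variance columns (e.g. all-dropout
    features) yield correlation 0 rather than NaN.
    """
    if pair.m < 3:
        raise InsufficientCellsError(
            f"subject {pair.subject_id!r} has {pair.m} cells; "
            "at least 3 are required to estimate correlations"
        )
    Xs, x_degen = _standardize_columns(pair.X)
    Gs, g_degen = _standardize_columns(pair.G)
    corr = Xs.T @ Gs
    np.clip(corr, -1.0, 1.0, out=corr)
    if x_degen.any():
        corr[x_degen, :] = 0.0
    if g_degen.any():
        corr[:, g_degen] = 0.0
    return corr


def build_tensor_set(study: StudyData) -> CorrelationTensorSet:
    """Build the ``(n, q, p)`` predictor tensor set in subject order."""
    mats = []
    for pair in study.subjects:
        _, x_degen = _standardize_columns(pair.X)
        _, g_degen = _standardize_columns(pair.G)
        frac = (x_degen.sum() + g_degen.sum()) / (x_degen.size + g_degen.size)
        if frac > 0:
            logger.debug(
                "subject %s: %.1f%% zero-variance feature columns",
                pair.subject_id, 100 * frac,
            )
        mats.append(subject_correlation(pair))
    return CorrelationTensorSet(Z=np.stack(mats, axis=0),
                                subject_ids=study.subject_ids)
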