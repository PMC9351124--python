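"""Dense tensor containers and the multilinear-algebra primitives used by
the rank-1 tensor regression engine.

A *D*-dimensional tensor is stored as a :class:`numpy.ndarray` with shape
``(p_1, ..., p_D)``.  The public contracts follow the standard CP/Kolda
conventions: ``vec`` stacks entries with the **first index varying
fastest** (column-major), and the mode-*d* matricization places dimension
*d* on the rows with the remaining indices enumerated column-major.
Indices are 1-based in the mathematical contracts and 0-based in code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FactorSet",
    "outer_product",
    "vec",
    "unvec",
    "matricize",
    "fold",
    "inner_product",
    "mode_d_product",
    "from_factors",
]


def outer_product(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Outer product ``b_1 ∘ b_2 ∘ ... ∘ b_D`` of D vectors.

    The result has shape ``(len(b_1), ..., len(b_D))`` and entry
    ``(i_1, ..., i_D)`` equal to ``prod_d b_d[i_d]``.
    """
    if len(vectors) == 0:
        raise ValueError("outer_product requires at least one vector")
    arrays = [np.asarray(v, dtype=float) for v in vectors]
    for v in arrays:
        if v.ndim != 1 or v.size == 0:
            raise ValueError("outer_product arguments must be nonempty 1-D vectors")
    out = arrays[0]
    for v in arrays[1:]:
        out = np.multiply.outer(out, v)
    return out


def vec(tensor: np.ndarray) -> np.ndarray:
    """Column-major vectorization: entry ``1 + sum_d (i_d - 1) prod_{d'<d} p_d'``
    of the result holds tensor entry ``(i_1, ..., i_D)``."""
    return np.asarray(tensor, dtype=float).reshape(-1, order="F")


def unvec(values: np.ndarray, dims: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`vec` for the given dimension extents."""
    dims = tuple(int(d) for d in dims)
    values = np.asarray(values, dtype=float)
    if values.size != int(np.prod(dims)):
        raise ValueError(
            f"cannot reshape {values.size} values into dims {dims}"
        )
    return values.reshape(dims, order="F")


def matricize(tensor: np.ndarray, d: int) -> np.ndarray:
    """Mode-*d* matricization (``d`` is 0-based here).

    Returns a ``p_d × prod_{d'≠d} p_d'`` matrix whose columns enumerate the
    non-*d* indices column-major (first remaining index fastest).
    """
    tensor = np.asarray(tensor, dtype=float)
    if not 0 <= d < tensor.ndim:
        raise ValueError(f"mode {d} out of range for a {tensor.ndim}-D tensor")
    return np.moveaxis(tensor, d, 0).reshape(tensor.shape[d], -1, order="F")


def fold(matrix: np.ndarray, d: int, dims: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`matricize`: rebuild the tensor of extents ``dims``
    from its mode-*d* unfolding."""
    dims = tuple(int(x) for x in dims)
    if not 0 <= d < len(dims):
        raise ValueError(f"mode {d} out of range for dims {dims}")
    rest = tuple(dims[i] for i in range(len(dims)) if i != d)
    arr = np.asarray(matrix, dtype=float).reshape((dims[d],) + rest, order="F")
    return np.moveaxis(arr, 0, d)


def inner_product(a: np.ndarray, b: np.ndarray) -> float:
    """Tensor inner product ``⟨A, B⟩ = Σ a_{i_1..i_D} b_{i_1..i_D}``;
    identical to ``dot(vec(A), vec(B))``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.dot(a.reshape(-1), b.reshape(-1)))


def mode_d_product(tensor: np.ndarray, u: np.ndarray, d: int) -> np.ndarray:
    """d-mode product ``T ×_d U``: contracts dimension *d* of the tensor with
    the columns of the ``q × p_d`` matrix ``U``, replacing extent ``p_d``
    by ``q``."""
    tensor = np.asarray(tensor, dtype=float)
    u = np.asarray(u, dtype=float)
    if not 0 <= d < tensor.ndim:
        raise ValueError(f"mode {d} out of range for a {tensor.ndim}-D tensor")
    if u.ndim != 2 or u.shape[1] != tensor.shape[d]:
        raise ValueError(
            f"matrix of shape {u.shape} cannot contract dimension {d} "
            f"of extent {tensor.shape[d]}"
        )
    moved = np.moveaxis(tensor, d, -1)
    result = moved @ u.T
    return np.moveaxis(result, -1, d)


@dataclass(frozen=True)
class FactorSet:
    """Per-dimension factor matrices of a rank-R CP representation.

    ``factors[d]`` has shape ``(p_d, R)``; column ``r`` is the dimension-*d*
    vector of the ``r``-th rank-1 component.
    """

    factors: tuple[np.ndarray, ...]

    def __init__(self, factors: Sequence[np.ndarray]):
        mats = tuple(np.atleast_2d(np.asarray(f, dtype=float)) for f in factors)
        if len(mats) == 0:
            raise ValueError("FactorSet requires at least one factor matrix")
        ranks = {m.shape[1] for m in mats}
        if len(ranks) != 1:
            raise ValueError(f"inconsistent factor ranks: {sorted(ranks)}")
        object.__setattr__(self, "factors", mats)

    @property
    def rank(self) -> int:
        return self.factors[0].shape[1]

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(m.shape[0] for m in self.factors)


def from_factors(factor_set: FactorSet | Sequence[np.ndarray]) -> np.ndarray:
    """Kruskal reconstruction ``[[Z_1, ..., Z_D]] = Σ_r z_1^(r) ∘ ... ∘ z_D^(r)``."""
    if not isinstance(factor_set, FactorSet):
        factor_set = FactorSet(factor_set)
    out = np.zeros(factor_set.dims)
    for r in range(factor_set.rank):
        out += outer_product([m[:, r] for m in factor_set.factors])
    return out
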