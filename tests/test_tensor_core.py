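"""Tensor primitives checked against brute-force index-formula oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moscato.tensor_core import (FactorSet, fold, from_factors, inner_product,
                                 matricize, mode_d_product, outer_product,
                                 unvec, vec)


def loop_outer(vectors):
    dims = tuple(len(v) for v in vectors)
    out = np.empty(dims)
    for idx in itertools.product(*(range(d) for d in dims)):
        out[idx] = np.prod([v[i] for v, i in zip(vectors, idx)])
    return out


def loop_vec(tensor):
    """Column-major stacking by the explicit index formula (1-based in the
    math, 0-based here): j = sum_d i_d * prod_{d'<d} p_d'."""
    dims = tensor.shape
    out = np.empty(int(np.prod(dims)))
    for idx in itertools.product(*(range(d) for d in dims)):
        j = 0
        stride = 1
        for d, i in enumerate(idx):
            j += i * stride
            stride *= dims[d]
        out[j] = tensor[idx]
    return out


def loop_matricize(tensor, d):
    dims = tensor.shape
    rest = [dd for dd in range(tensor.ndim) if dd != d]
    out = np.empty((dims[d], int(np.prod([dims[r] for r in rest], initial=1))))
    for idx in itertools.product(*(range(dd) for dd in dims)):
        j = 0
        stride = 1
        for dd in rest:
            j += idx[dd] * stride
            stride *= dims[dd]
        out[idx[d], j] = tensor[idx]
    return out


rng = np.random.default_rng(1234)


class TestOuterProduct:
    def test_two_vector_example(self):
        np.testing.assert_array_equal(outer_product([[1, 2], [3, 4]]),
                                      [[3, 4], [6, 8]])

    def test_singleton_identity(self):
        assert outer_product([[1], [1], [1]]).shape == (1, 1, 1)
        assert outer_product([[1], [1], [1]])[0, 0, 0] == 1

    def test_matches_loop_oracle(self):
        vectors = [np.array([1.0, 2.0]), np.array([1.0, 10.0]), np.array([2.0])]
        np.testing.assert_allclose(outer_product(vectors), loop_outer(vectors))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            outer_product([])
        with pytest.raises(ValueError):
            outer_product([np.array([])])


class TestVecMatricize:
    def test_vec_2x2_column_major(self):
        np.testing.assert_array_equal(vec(np.array([[1, 2], [3, 4]])),
                                      [1, 3, 2, 4])

    def test_vec_1d_identity(self):
        v = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(vec(v), v)

    def test_vec_matches_index_formula(self):
        t = rng.standard_normal((2, 3, 2))
        np.testing.assert_allclose(vec(t), loop_vec(t))

    def test_matricize_mode0_is_identity_for_matrix(self):
        m = rng.standard_normal((2, 2))
        np.testing.assert_array_equal(matricize(m, 0), m)
        np.testing.assert_array_equal(matricize(m, 1), m.T)

    def test_matricize_2x2x2_example(self):
        t = unvec(np.arange(1.0, 9.0), (2, 2, 2))
        np.testing.assert_array_equal(matricize(t, 0),
                                      [[1, 3, 5, 7], [2, 4, 6, 8]])

    def test_matricize_matches_index_formula(self):
        t = rng.standard_normal((3, 2, 4))
        for d in range(3):
            np.testing.assert_allclose(matricize(t, d), loop_matricize(t, d))

    def test_mode_out_of_range(self):
        with pytest.raises(ValueError):
            matricize(np.zeros((2, 2)), 2)


class TestInnerProduct:
    def test_sum_of_squares(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert inner_product(a, a) == 30

    def test_zero_tensor(self):
        a = rng.standard_normal((3, 2))
        assert inner_product(a, np.zeros_like(a)) == 0

    def test_matches_triple_loop(self):
        a = rng.standard_normal((3, 2, 2))
        b = rng.standard_normal((3, 2, 2))
        expected = sum(a[i, j, k] * b[i, j, k]
                       for i in range(3) for j in range(2) for k in range(2))
        assert inner_product(a, b) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            inner_product(np.zeros((2, 2)), np.zeros((2, 3)))


class TestModeProduct:
    def test_column_sums(self):
        t = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(mode_d_product(t, np.array([[1.0, 1.0]]), 0),
                                      [[4.0, 6.0]])

    def test_identity_matrix(self):
        t = rng.standard_normal((3, 4))
        np.testing.assert_allclose(mode_d_product(t, np.eye(4), 1), t)

    def test_matches_loop_oracle(self):
        t = rng.standard_normal((2, 3))
        u = rng.standard_normal((2, 3))
        result = mode_d_product(t, u, 1)
        expected = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                expected[i, j] = sum(t[i, k] * u[j, k] for k in range(3))
        np.testing.assert_allclose(result, expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mode_d_product(np.zeros((2, 3)), np.zeros((2, 4)), 1)


class TestFactorSet:
    def test_rank1_equals_outer_product(self):
        fs = FactorSet([np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]])])
        np.testing.assert_array_equal(from_factors(fs), [[3, 4], [6, 8]])

    def test_rank2_identity_construction(self):
        cols = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(from_factors(FactorSet([cols, cols])),
                                      np.eye(2))

    def test_zero_column_annihilates(self):
        a = rng.standard_normal((3, 2))
        b = rng.standard_normal((4, 2))
        a2, b2 = a.copy(), b.copy()
        a2[:, 1] = 0.0
        np.testing.assert_allclose(
            from_factors(FactorSet([a2, b2])),
            from_factors(FactorSet([a[:, :1], b[:, :1]])))

    def test_inconsistent_ranks_rejected(self):
        with pytest.raises(ValueError):
            FactorSet([np.zeros((3, 2)), np.zeros((4, 3))])

    def test_reconstruction_of_constructed_rank2(self):
        factors = [rng.standard_normal((d, 2)) for d in (3, 4, 2)]
        t = sum(loop_outer([f[:, r] for f in factors]) for r in range(2))
        np.testing.assert_allclose(from_factors(FactorSet(factors)), t,
                                   atol=1e-12)


@st.composite
def small_tensors(draw):
    ndim = draw(st.integers(1, 4))
    dims = tuple(draw(st.integers(1, 4)) for _ in range(ndim))
    seed = draw(st.integers(0, 2**31 - 1))
    return np.random.default_rng(seed).standard_normal(dims)


@settings(max_examples=50, deadline=None)
@given(small_tensors())
def test_vec_unvec_round_trip(t):
    np.testing.assert_array_equal(unvec(vec(t), t.shape), t)


@settings(max_examples=50, deadline=None)
@given(small_tensors(), st.integers(0, 3))
def test_matricize_fold_round_trip(t, d):
    d = d % t.ndim
    np.testing.assert_array_equal(fold(matricize(t, d), d, t.shape), t)


@settings(max_examples=50, deadline=None)
@given(small_tensors(), st.integers(0, 2**31 - 1))
def test_inner_product_equals_vec_dot(t, seed):
    other = np.random.default_rng(seed).standard_normal(t.shape)
    assert inner_product(t, other) == pytest.approx(
        float(np.dot(vec(t), vec(other))), rel=1e-12, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_rank1_inner_product_is_bilinear_form(seed):
    """<b1 ∘ b2, Z> == b1' Z b2: the 2-D rank-1 reduction used by the
    regression engine."""
    r = np.random.default_rng(seed)
    b1, b2 = r.standard_normal(3), r.standard_normal(4)
    z = r.standard_normal((3, 4))
    assert inner_product(outer_product([b1, b2]), z) == pytest.approx(
        float(b1 @ z @ b2), rel=1e-10, abs=1e-10)
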