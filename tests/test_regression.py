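"""Block-relaxation tensor GLM: closed-form and construct-and-recover
oracles, constraint contracts, and identifiability properties."""

import numpy as np
import pytest

from moscato.regression import (ElasticNetSpec, MoscatoFitError,
                                Rank1TensorGLM, TensorFit, _gaussian_block,
                                fit_rank1_tensor_glm, linear_predictor)
from moscato.tensor_core import inner_product, outer_product, vec


def make_fit(beta_X, beta_G, beta0=0.0, cov=()):
    return TensorFit(beta0=beta0, covariate_coefs=np.asarray(cov, float),
                     beta_X=np.asarray(beta_X, float),
                     beta_G=np.asarray(beta_G, float), family="gaussian")


class TestLinearPredictor:
    def test_picks_single_entry(self):
        fit = make_fit([1, 0], [0, 1])
        assert linear_predictor(fit, np.array([[1.0, 2.0], [3.0, 4.0]])) == 2.0

    def test_all_zero_betas_return_intercept(self):
        fit = make_fit([0, 0], [0, 0], beta0=1.5)
        assert linear_predictor(fit, np.zeros((2, 2))) == 1.5

    def test_matches_tensor_core_inner_product(self):
        rng = np.random.default_rng(8)
        fit = make_fit(rng.standard_normal(3), rng.standard_normal(4))
        z = rng.standard_normal((3, 4))
        expected = inner_product(outer_product([fit.beta_X, fit.beta_G]), z)
        assert linear_predictor(fit, z) == pytest.approx(expected, abs=1e-12)

    def test_covariates_enter_linearly(self):
        fit = make_fit([1.0], [1.0], beta0=1.0, cov=[2.0])
        assert linear_predictor(fit, np.array([[3.0]]), np.array([0.5])) == \
            pytest.approx(1.0 + 1.0 + 3.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            linear_predictor(make_fit([1, 0], [0, 1]), np.zeros((3, 3)))


class TestGaussianBlockUpdate:
    def test_ols_limit_recovers_truth(self):
        """Noiseless y with wide-open penalty: the weakest-penalty path
        point approaches ordinary least squares."""
        rng = np.random.default_rng(9)
        W = rng.standard_normal((50, 5))
        beta = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        y = W @ beta
        coef, gamma = _gaussian_block(W, y, None, ElasticNetSpec(0.5, 5),
                                      n_alphas=80, path_eps=1e-9,
                                      path_tol=1e-12)
        np.testing.assert_allclose(coef, beta, atol=1e-6)
        assert gamma[0] == pytest.approx(0.0, abs=1e-8)

    def test_support_cap_of_one(self):
        rng = np.random.default_rng(10)
        W = rng.standard_normal((30, 8))
        y = rng.standard_normal(30)
        coef, _ = _gaussian_block(W, y, None, ElasticNetSpec(0.7, 1),
                                  n_alphas=50, path_eps=1e-3, path_tol=1e-6)
        assert np.count_nonzero(coef) <= 1

    def test_lasso_on_orthonormal_design_is_soft_thresholding(self):
        """With alpha=1 and orthonormal columns, every path solution is the
        soft-thresholded OLS vector; replicate the path's own pick rule on
        the closed form and compare."""
        rng = np.random.default_rng(11)
        raw = rng.standard_normal((40, 6))
        raw -= raw.mean(axis=0, keepdims=True)
        q_mat, _ = np.linalg.qr(raw)
        W = q_mat  # orthonormal, column-centered (intercept-orthogonal)
        y = rng.standard_normal(40)
        n = 40
        cap = 3
        spec = ElasticNetSpec(1.0, cap)
        coef, _ = _gaussian_block(W, y, None, spec, n_alphas=60,
                                  path_eps=1e-3, path_tol=1e-10)
        yc = y - y.mean()
        c = W.T @ yc  # OLS coefficients on the residualized design
        alpha_max = np.max(np.abs(W.T @ yc)) / n
        alphas = np.geomspace(alpha_max * 1.0001, alpha_max * 1e-3, 60)
        best = None
        for a in alphas:  # strong -> weak, keep largest support <= cap
            soft = np.sign(c) * np.maximum(np.abs(c) - n * a, 0.0)
            nnz = np.count_nonzero(soft)
            if 0 < nnz <= cap and (best is None or
                                   nnz >= np.count_nonzero(best)):
                best = soft
        np.testing.assert_allclose(coef, best, atol=1e-6)

    def test_unpenalized_covariates_via_residualization(self):
        rng = np.random.default_rng(12)
        W = rng.standard_normal((60, 3))
        U = rng.standard_normal((60, 2))
        beta = np.array([1.0, 0.0, -1.0])
        lam = np.array([2.0, -3.0])
        y = 0.7 + W @ beta + U @ lam
        coef, gamma = _gaussian_block(W, y, U, ElasticNetSpec(0.5, 3),
                                      n_alphas=80, path_eps=1e-9,
                                      path_tol=1e-12)
        np.testing.assert_allclose(coef, beta, atol=1e-5)
        np.testing.assert_allclose(gamma, [0.7, 2.0, -3.0], atol=1e-5)


class TestRank1Fit:
    def test_scalar_tensor_reduces_to_simple_regression(self):
        rng = np.random.default_rng(13)
        z = rng.standard_normal(30)
        y = 2.0 + 3.0 * z
        fit = fit_rank1_tensor_glm(z[:, None, None], y,
                                   path_eps=1e-9, path_tol=1e-12)
        slope = fit.beta_X[0] * fit.beta_G[0]
        assert slope == pytest.approx(3.0, abs=1e-5)
        assert fit.beta0 == pytest.approx(2.0, abs=1e-5)

    def test_noiseless_rank1_construct_and_recover(self):
        rng = np.random.default_rng(14)
        n, q, p = 40, 8, 10
        Z = rng.standard_normal((n, q, p))
        b_x = np.zeros(q)
        b_x[[1, 4, 6]] = [2.0, -1.5, 1.0]
        b_g = np.zeros(p)
        b_g[[0, 3, 5, 9]] = [1.0, 0.5, -2.0, 1.5]
        y = np.einsum("nqp,q,p->n", Z, b_x, b_g)
        model = Rank1TensorGLM(alpha_X=0.5, alpha_G=0.5, max_X=3, max_G=4,
                               path_eps=1e-9, path_tol=1e-12)
        model.fit(Z, y)
        assert set(np.flatnonzero(model.beta_X_)) == {1, 4, 6}
        assert set(np.flatnonzero(model.beta_G_)) == {0, 3, 5, 9}
        pred = model.decision_function(Z)
        np.testing.assert_allclose(pred, y, atol=1e-6 * np.abs(y).max())

    def test_scale_indeterminacy_yields_identical_predictor(self):
        rng = np.random.default_rng(15)
        fit = make_fit(rng.standard_normal(3), rng.standard_normal(5))
        Z = rng.standard_normal((7, 3, 5))
        tau = 3.7
        rescaled = make_fit(tau * fit.beta_X, fit.beta_G / tau)
        np.testing.assert_allclose(linear_predictor(fit, Z),
                                   linear_predictor(rescaled, Z), atol=1e-10)

    def test_beta_g_normalized_to_unit_norm(self):
        rng = np.random.default_rng(16)
        Z = rng.standard_normal((20, 4, 6))
        y = Z[:, 0, 0] + 0.1 * rng.standard_normal(20)
        model = Rank1TensorGLM(max_X=4, max_G=6).fit(Z, y)
        assert np.linalg.norm(model.beta_G_) == pytest.approx(1.0, abs=1e-10)

    def test_support_caps_always_hold(self):
        rng = np.random.default_rng(17)
        Z = rng.standard_normal((25, 6, 9))
        y = rng.standard_normal(25)
        model = Rank1TensorGLM(alpha_X=0.3, alpha_G=0.9, max_X=2, max_G=3)
        model.fit(Z, y)
        assert np.count_nonzero(model.beta_X_) <= 2
        assert np.count_nonzero(model.beta_G_) <= 3

    def test_unpenalized_deviance_trace_monotone(self):
        """Exact block minimization of the gaussian deviance is monotone;
        with caps wide open and the penalty path driven to its floor, the
        recorded trace must be non-increasing up to tiny slack."""
        rng = np.random.default_rng(18)
        Z = rng.standard_normal((30, 3, 4))
        y = rng.standard_normal(30)
        model = Rank1TensorGLM(max_X=3, max_G=4, path_eps=1e-10,
                               path_tol=1e-12, tol=1e-10, max_iter=40)
        model.fit(Z, y)
        trace = np.array(model.deviance_trace_)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_2x2_objective_beats_brute_force_grid(self):
        """Local-maximum sanity: the converged unpenalized fit is at least
        as good as the best rank-1 coefficient set on a coarse grid."""
        rng = np.random.default_rng(19)
        Z = rng.standard_normal((30, 2, 2))
        y = rng.standard_normal(30)
        model = Rank1TensorGLM(max_X=2, max_G=2, path_eps=1e-9,
                               path_tol=1e-12)
        model.fit(Z, y)
        rss_fit = model.deviance_trace_[-1]
        grid = np.arange(-2.0, 2.05, 0.1)
        bx = np.array(np.meshgrid(grid, grid)).reshape(2, -1).T  # (1681, 2)
        Zf = Z.reshape(30, 4)
        yc = y - y.mean()
        best = np.inf
        for g_pair in bx:
            B = (bx[:, :, None] * g_pair[None, None, :]).reshape(-1, 4)
            pred = Zf @ B.T
            pred -= pred.mean(axis=0, keepdims=True)
            rss = np.sum((yc[:, None] - pred) ** 2, axis=0)
            best = min(best, float(rss.min()))
        assert rss_fit <= best + 1e-3

    def test_rank1_coefficients_valid_in_vectorized_design(self):
        """Plugging vec(beta_X ∘ beta_G) into the naively vectorized GLM
        design reproduces the tensor fit's linear predictor."""
        rng = np.random.default_rng(20)
        Z = rng.standard_normal((40, 3, 4))
        y = Z[:, 1, 2] + 0.05 * rng.standard_normal(40)
        model = Rank1TensorGLM(max_X=3, max_G=4, path_eps=1e-9,
                               path_tol=1e-12).fit(Z, y)
        coef_vec = vec(outer_product([model.beta_X_, model.beta_G_]))
        design = np.stack([vec(np.asarray(Zi)) for Zi in Z])
        np.testing.assert_allclose(design @ coef_vec + model.intercept_,
                                   model.decision_function(Z), atol=1e-4)

    def test_binomial_family_fits_and_respects_caps(self):
        rng = np.random.default_rng(21)
        n, q, p = 60, 4, 5
        Z = rng.standard_normal((n, q, p))
        eta = 2.0 * Z[:, 0, 0] - 1.5 * Z[:, 0, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        model = Rank1TensorGLM(family="binomial", max_X=2, max_G=3).fit(Z, y)
        assert np.count_nonzero(model.beta_X_) <= 2
        assert np.count_nonzero(model.beta_G_) <= 3
        acc = np.mean(model.predict(Z) == y)
        assert acc > 0.6

    @pytest.mark.parametrize("kwargs,match", [
        (dict(family="poisson"), "family"),
        (dict(alpha_X=1.5), "alpha"),
    ])
    def test_invalid_parameters_rejected(self, kwargs, match):
        Z = np.zeros((5, 2, 2))
        y = np.zeros(5)
        with pytest.raises(ValueError, match=match):
            Rank1TensorGLM(**kwargs).fit(Z, y)

    def test_binomial_requires_binary_outcome(self):
        Z = np.random.default_rng(22).standard_normal((10, 2, 2))
        with pytest.raises(ValueError, match="0/1"):
            Rank1TensorGLM(family="binomial").fit(Z, np.linspace(0, 2, 10))
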