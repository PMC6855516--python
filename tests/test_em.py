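"""Sufficient-statistics EM for Gaussians under block missingness.

Oracles: ordinary least squares via explicit normal equations, conditional
moments by adaptive quadrature of the full joint density (never the
conditional-normal formulas used by the implementation), and marginal
densities by numerical integration over the missing coordinate.
"""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal

from segem.core import MissingnessPattern, MomentMatrix
from segem.em import (
    DataBlock,
    EMConfig,
    em_fit_state,
    expected_moments_for_cell,
    init_moment_matrix,
    marginal_log_density,
    moments_from_V,
    regression_from_moments,
    regression_from_params,
)


def gram_matrix(X: np.ndarray) -> np.ndarray:
    """Exact augmented moment matrix of fully observed rows."""
    n, p = X.shape
    V = np.zeros((p + 1, p + 1))
    V[0, 0] = n
    V[0, 1:] = X.sum(axis=0)
    V[1:, 0] = X.sum(axis=0)
    V[1:, 1:] = X.T @ X
    return V


class TestInitMomentMatrix:
    @pytest.mark.parametrize("p", [1, 2, 7])
    def test_identity(self, p):
        assert np.array_equal(init_moment_matrix(p), np.eye(p + 1))

    def test_implied_moments_of_identity(self):
        n, mean, cov = moments_from_V(init_moment_matrix(3))
        assert n == 1.0
        assert np.allclose(mean, 0.0)
        assert np.allclose(cov, np.eye(3))


class TestRegressionFromMoments:
    def test_identity_V_gives_zero_map(self):
        pat = MissingnessPattern(observed=(0,), cells=(0,), n_marks=2)
        reg = regression_from_moments(init_moment_matrix(2), pat)
        assert np.allclose(reg.alpha, 0.0)
        assert np.allclose(reg.beta, 0.0)

    def test_independence_gives_beta_zero_alpha_mean(self):
        # diagonal covariance, nonzero means
        mean = np.array([2.0, -1.0, 0.5])
        cov = np.diag([1.0, 4.0, 2.0])
        reg = regression_from_params(mean, cov, observed=(0, 2), missing=(1,), ridge=0)
        assert np.allclose(reg.beta, 0.0)
        assert np.allclose(reg.alpha, mean[[1]])

    def test_matches_normal_equations_oracle(self):
        # 4 fully observed 2-mark rows; regression of mark2 on mark1
        X = np.array([[1.0, 2.0], [2.0, 2.5], [3.0, 4.5], [4.0, 5.0]])
        V = MomentMatrix(gram_matrix(X))
        pat = MissingnessPattern(observed=(0,), cells=(0,), n_marks=2)
        reg = regression_from_moments(V, pat, ridge=0)
        # oracle: OLS normal equations on the raw rows
        A = np.column_stack([np.ones(4), X[:, 0]])
        coef = np.linalg.solve(A.T @ A, A.T @ X[:, 1])
        assert reg.alpha[0] == pytest.approx(coef[0], abs=1e-10)
        assert reg.beta[0, 0] == pytest.approx(coef[1], abs=1e-10)


def quadrature_conditional_moments(x_obs, mean, cov, obs_idx, mis_idx):
    """E[x_m | x_o], E[x_m^2 | x_o], E[x_m x_o | x_o] by integrating the joint.

    Only the full joint density is used (no conditional-normal formulas);
    one missing coordinate.
    """
    (m,) = mis_idx
    full = multivariate_normal(mean, cov)

    def joint(xm):
        x = np.empty(len(mean))
        x[list(obs_idx)] = x_obs
        x[m] = xm
        return full.pdf(x)

    lo = mean[m] - 15 * np.sqrt(cov[m, m])
    hi = mean[m] + 15 * np.sqrt(cov[m, m])
    z = integrate.quad(joint, lo, hi, epsabs=1e-14, limit=200)[0]
    e1 = integrate.quad(lambda xm: xm * joint(xm), lo, hi, epsabs=1e-14, limit=200)[0] / z
    e2 = integrate.quad(lambda xm: xm**2 * joint(xm), lo, hi, epsabs=1e-14, limit=200)[0] / z
    return e1, e2


class TestExpectedMoments:
    def test_fully_observed_is_exact_gram(self, rng):
        X = rng.normal(size=(6, 3))
        block = DataBlock(observed=(0, 1, 2), X=X)
        from segem.core import RegressionMap

        dummy = RegressionMap(np.zeros(0), np.zeros((0, 3)))
        for variant in ("regression_only", "corrected"):
            V = expected_moments_for_cell(block, dummy, p=3, variant=variant)
            assert np.allclose(V, gram_matrix(X), atol=1e-12)

    def test_beta_zero_hand_expansion(self):
        # one missing mark, beta = 0, alpha = c: missing sum = n*c; the
        # missing x missing entry differs between variants by n*sigma2_cond
        from segem.core import RegressionMap

        X = np.array([[1.0], [2.0], [3.0]])
        c, s2 = 1.5, 0.7
        block = DataBlock(observed=(0,), X=X)
        reg = RegressionMap(np.array([c]), np.zeros((1, 1)), np.array([[s2]]))
        V_lit = expected_moments_for_cell(block, reg, p=2, variant="regression_only")
        V_cor = expected_moments_for_cell(block, reg, p=2, variant="corrected")
        n = 3
        for V in (V_lit, V_cor):
            assert V[0, 2] == pytest.approx(n * c)
            assert V[2, 1] == pytest.approx(c * X.sum())
        assert V_lit[2, 2] == pytest.approx(n * c * c)
        assert V_cor[2, 2] - V_lit[2, 2] == pytest.approx(n * s2)

    def test_matches_quadrature_oracle(self):
        # n=3 rows, p=2, mark 2 missing; expectations under a known Gaussian
        mean = np.array([0.3, -0.6])
        cov = np.array([[1.2, 0.7], [0.7, 1.5]])
        X = np.array([[0.1], [1.4], [-0.9]])
        block = DataBlock(observed=(0,), X=X)
        reg = regression_from_params(mean, cov, (0,), (1,), ridge=0)
        V = expected_moments_for_cell(block, reg, p=2, variant="corrected")

        e1s, e2s, exs = 0.0, 0.0, 0.0
        for xo in X[:, 0]:
            e1, e2 = quadrature_conditional_moments([xo], mean, cov, (0,), (1,))
            e1s += e1
            e2s += e2
            exs += e1 * xo
        assert V[0, 2] == pytest.approx(e1s, abs=1e-10)
        assert V[2, 2] == pytest.approx(e2s, abs=1e-10)
        assert V[1, 2] == pytest.approx(exs, abs=1e-10)

    def test_pattern_consistency_sum_over_groups(self, rng):
        # V^k of a union of cell groups = sum of the groups' V^k
        mean = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        reg = regression_from_params(mean, cov, (0, 2), (1,), ridge=0)
        X = rng.normal(size=(10, 2))
        w = rng.random(10)
        whole = DataBlock((0, 2), X, w)
        part1 = DataBlock((0, 2), X[:4], w[:4])
        part2 = DataBlock((0, 2), X[4:], w[4:])
        V_whole = expected_moments_for_cell(whole, reg, p=3)
        V_sum = expected_moments_for_cell(part1, reg, p=3) + expected_moments_for_cell(
            part2, reg, p=3
        )
        assert np.allclose(V_whole, V_sum, atol=1e-10)


class TestEMFitState:
    def test_fully_observed_converges_immediately_to_mle(self, rng):
        X = rng.normal(size=(50, 3)) * [1.0, 2.0, 0.5] + [1.0, -2.0, 0.0]
        w = rng.random(50)
        res = em_fit_state([DataBlock((0, 1, 2), X, w)], p=3, config=EMConfig(ridge=0))
        mu = w @ X / w.sum()
        Xc = X - mu
        Sigma = Xc.T @ (Xc * w[:, None]) / w.sum()
        assert np.allclose(res.mean, mu, atol=1e-12)
        assert np.allclose(res.cov, Sigma, atol=1e-12)
        assert res.n_iter <= 2  # second pass only confirms convergence

    @staticmethod
    def _mcar_instance(seed=7, n=2000, miss_frac=0.3):
        rng = np.random.default_rng(seed)
        mean = np.array([1.0, -0.5])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        X = rng.multivariate_normal(mean, cov, size=n)
        miss = rng.random(n) < miss_frac
        blocks = [
            DataBlock((0, 1), X[~miss]),
            DataBlock((0,), X[miss][:, :1]),
        ]
        return blocks, mean, cov, n

    def test_corrected_variant_recovers_truth(self):
        blocks, mean, cov, n = self._mcar_instance()
        res = em_fit_state(blocks, p=2, config=EMConfig(variant="corrected"))
        se = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(res.mean - mean) < 3 * se)
        assert np.all(np.abs(res.cov - cov) / np.abs(cov) < 0.15)

    def test_regression_only_shrinks_missing_variance(self):
        blocks, *_ = self._mcar_instance()
        res_cor = em_fit_state(blocks, p=2, config=EMConfig(variant="corrected"))
        res_lit = em_fit_state(blocks, p=2, config=EMConfig(variant="regression_only"))
        assert res_lit.cov[1, 1] <= res_cor.cov[1, 1]

    def test_loglik_monotone_corrected(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            mean = rng.normal(size=2)
            A = rng.normal(size=(2, 2))
            cov = A @ A.T + 0.5 * np.eye(2)
            X = rng.multivariate_normal(mean, cov, size=60)
            blocks = [DataBlock((0, 1), X[:40]), DataBlock((0,), X[40:, :1])]
            res = em_fit_state(
                blocks, p=2, config=EMConfig(variant="corrected", track_loglik=True)
            )
            ll = np.array(res.loglik_trace)
            assert np.all(np.diff(ll) >= -1e-8 * np.maximum(1.0, np.abs(ll[:-1])))

    def test_effective_count_too_small_errors(self, rng):
        X = rng.normal(size=(2, 3))
        with pytest.raises(ValueError, match="effective count"):
            em_fit_state([DataBlock((0, 1, 2), X)], p=3)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(80, 3))
        blocks = [DataBlock((0, 1, 2), X[:50]), DataBlock((0, 2), X[50:, [0, 2]])]
        res = em_fit_state(blocks, p=3)
        # relabel marks by permutation (0,1,2) -> (2,0,1)
        perm = np.array([2, 0, 1])  # new index of each old mark
        blocks_p = [
            DataBlock(tuple(np.sort(perm[[0, 1, 2]])), X[:50][:, np.argsort(perm)]),
            DataBlock(tuple(np.sort(perm[[0, 2]])), X[50:, [0, 2]][:, np.argsort(np.argsort(perm[[0, 2]]))]),
        ]
        res_p = em_fit_state(blocks_p, p=3)
        assert np.allclose(res_p.mean[perm], res.mean, atol=1e-8)
        assert np.allclose(res_p.cov[np.ix_(perm, perm)], res.cov, atol=1e-8)


class TestMarginalLogDensity:
    def test_all_marks_equals_full_density(self, rng):
        mean = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        x = rng.normal(size=3)
        got = marginal_log_density(x, (0, 1, 2), mean, cov)
        assert got == pytest.approx(multivariate_normal(mean, cov).logpdf(x))

    def test_single_mark_is_univariate(self, rng):
        mean = np.array([1.0, -2.0])
        cov = np.array([[2.0, 0.3], [0.3, 0.5]])
        x = 0.7
        got = marginal_log_density([x], (1,), mean, cov)
        from scipy.stats import norm

        assert got == pytest.approx(norm(mean[1], np.sqrt(cov[1, 1])).logpdf(x))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadrature_over_missing_coordinate(self, seed):
        rng = np.random.default_rng(seed)
        mean = rng.normal(size=3)
        A = rng.normal(size=(3, 3)) * 0.8
        cov = A @ A.T + np.eye(3)
        x_obs = rng.normal(size=2)
        got = marginal_log_density(x_obs, (0, 1), mean, cov)
        full = multivariate_normal(mean, cov)

        def joint(x2):
            return full.pdf(np.array([x_obs[0], x_obs[1], x2]))

        lo = mean[2] - 15 * np.sqrt(cov[2, 2])
        hi = mean[2] + 15 * np.sqrt(cov[2, 2])
        expected = np.log(integrate.quad(joint, lo, hi, epsabs=1e-14, limit=200)[0])
        assert got == pytest.approx(expected, abs=1e-6)
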