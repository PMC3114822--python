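import numpy as np
import pytest
from scipy import linalg

from mobilegam.smoothers import (ar_autocovariance, build_spatial_basis,
                                 build_univariate_basis, fit_penalized,
                                 smooth_pvalue, whiten_ar)

rng0 = np.random.default_rng(42)


class TestUnivariateBasis:
    def test_partition_of_unity_before_centering(self):
        x = rng0.uniform(0, 10, 300)
        sm = build_univariate_basis(x, k=10)
        B = sm.raw_basis(np.linspace(0, 10, 37))
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_linear_function_incurs_zero_penalty(self):
        x = np.linspace(0, 1, 200)
        sm = build_univariate_basis(x, k=8)
        # project f(x) = 3x - 1 onto the raw basis, then constrain
        B = sm.raw_basis(x)
        c, *_ = np.linalg.lstsq(B, 3 * x - 1, rcond=None)
        assert np.allclose(B @ c, 3 * x - 1, atol=1e-8)
        cz, *_ = np.linalg.lstsq(sm.design, (3 * x - 1) - (3 * x - 1).mean(),
                                 rcond=None)
        assert cz @ sm.penalty @ cz == pytest.approx(0.0, abs=1e-8)

    def test_constraint_removes_one_coefficient_and_centers(self):
        x = rng0.uniform(0, 5, 120)
        sm = build_univariate_basis(x, k=9)
        assert sm.design.shape[1] == 8
        coef = rng0.normal(size=8)
        assert abs((sm.design @ coef).mean()) < 1e-8

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_univariate_basis(np.ones(50), k=5)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_univariate_basis(np.tile([1.0, 2, 3, 4], 20), k=10)

    def test_log_transform_is_monotone_reparameterization(self):
        x = rng0.uniform(0, 500, 400)
        sm = build_univariate_basis(x, k=10, transform="log", offset=10.0)
        g = np.linspace(1, 480, 50)
        M = sm.predict_matrix(g)
        assert M.shape == (50, 9)
        assert np.all(np.isfinite(M))


class TestSpatialBasis:
    def _coords(self, n=400):
        return rng0.uniform(0, 100, size=(n, 2))

    def test_centered_over_observations(self):
        s = self._coords()
        sm = build_spatial_basis(s, k=20)
        coef = rng0.normal(size=sm.design.shape[1])
        assert abs((sm.design @ coef).mean()) < 1e-8

    def test_affine_surface_zero_penalty(self):
        s = self._coords()
        sm = build_spatial_basis(s, k=20)
        target = 0.3 * (s[:, 0] - s[:, 0].mean()) - 0.1 * (s[:, 1] - s[:, 1].mean())
        coef, *_ = np.linalg.lstsq(sm.design, target, rcond=None)
        assert np.allclose(sm.design @ coef, target, atol=1e-6)
        assert coef @ sm.penalty @ coef == pytest.approx(0.0, abs=1e-8)

    def test_k3_degenerates_to_affine_only(self):
        sm = build_spatial_basis(self._coords(), k=3)
        assert sm.design.shape[1] == 2
        assert np.allclose(sm.penalty, 0.0)

    def test_collinear_cloud_rejected(self):
        t = np.linspace(0, 1, 50)
        line = np.column_stack([t, 2 * t + 1])
        with pytest.raises(ValueError, match="collinear"):
            build_spatial_basis(line, k=10)

    def test_penalty_psd(self):
        sm = build_spatial_basis(self._coords(), k=25)
        w = np.linalg.eigvalsh(sm.penalty)
        assert w.min() >= -1e-10


class TestARWhitening:
    def test_autocovariance_matches_statsmodels(self):
        from statsmodels.tsa.arima_process import ArmaProcess
        phi = np.array([0.5, -0.2, 0.1])
        ours = ar_autocovariance(phi, 10, sigma2=1.3)
        ref = ArmaProcess(np.r_[1, -phi], [1]).acovf(11) * 1.3
        assert np.allclose(ours, ref, atol=1e-10)

    def test_whitened_series_has_identity_covariance(self):
        phi = np.array([0.6, -0.3])
        n = 40
        g = ar_autocovariance(phi, n - 1)
        Sigma = linalg.toeplitz(g)
        L = np.linalg.cholesky(Sigma)
        W = whiten_ar(np.eye(n), phi, [np.arange(n)])  # whitening matrix
        assert np.allclose(W @ Sigma @ W.T, np.eye(n), atol=1e-10)
        assert L is not None  # silence lint


class TestFitPenalized:
    def test_unpenalized_matches_normal_equations(self):
        n, p = 80, 5
        X = rng0.normal(size=(n, p))
        y = rng0.normal(size=n)
        fit = fit_penalized(y, X, [])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.beta, oracle, atol=1e-8)

    def test_infinite_penalty_collapses_to_null_space(self):
        x = rng0.uniform(0, 1, 300)
        y = np.sin(2 * np.pi * x) + rng0.normal(0, 0.2, 300)
        sm = build_univariate_basis(x, k=10)
        fit = fit_penalized(y, np.ones((300, 1)), [sm], lambdas=[np.inf])
        # only the (linear) null space survives: quadratic form vanishes
        assert sm.coef @ sm.penalty @ sm.coef < 1e-6
        # intercept-only information: fitted mean equals sample mean
        assert fit.fitted.mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_ar_zero_order_identical_to_independent(self):
        n = 200
        x = rng0.uniform(0, 1, n)
        y = np.sin(2 * np.pi * x) + rng0.normal(0, 0.3, n)
        sm1 = build_univariate_basis(x, k=8)
        sm2 = build_univariate_basis(x, k=8)
        f1 = fit_penalized(y, np.ones((n, 1)), [sm1], lambdas=[3.0])
        f2 = fit_penalized(y, np.ones((n, 1)), [sm2], lambdas=[3.0],
                           ar_phi=np.empty(0), groups=[np.arange(n)])
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_whitening_equals_explicit_gls_oracle(self, p):
        """Innovations-filter whitening must reproduce brute-force penalized
        GLS with the explicitly assembled AR covariance matrix."""
        rng = np.random.default_rng(p)
        n = 150
        phi = {1: [0.6], 2: [0.5, -0.2], 3: [0.5, -0.2, 0.1]}[p]
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        x = rng.uniform(0, 1, n)
        sm = build_univariate_basis(x, k=8)
        y = X @ [1, 0.5, -0.3] + np.sin(2 * np.pi * x) + rng.normal(0, 0.3, n)
        groups = [np.arange(0, 70), np.arange(70, 150)]
        lam = 4.0
        fit = fit_penalized(y, X, [sm], ar_phi=phi, groups=groups,
                            lambdas=[lam])

        g = ar_autocovariance(phi, 79)
        Sigma = linalg.block_diag(linalg.toeplitz(g[:70]),
                                  linalg.toeplitz(g[:80]))
        Si = np.linalg.inv(Sigma)
        Xa = np.column_stack([X, sm.design])
        S = np.zeros((Xa.shape[1],) * 2)
        Sn = sm.penalty / np.linalg.eigvalsh(sm.penalty)[-1]
        S[3:, 3:] = lam * Sn
        oracle = np.linalg.solve(Xa.T @ Si @ Xa + S, Xa.T @ Si @ y)
        assert np.abs(fit.beta - oracle).max() < 1e-6

    def test_edf_monotone_in_lambda(self):
        x = rng0.uniform(0, 1, 250)
        y = np.sin(2 * np.pi * x) + rng0.normal(0, 0.3, 250)
        edfs = []
        for lam in [1e-3, 1e-1, 10, 1e3, 1e5]:
            sm = build_univariate_basis(x, k=10)
            fit = fit_penalized(y, np.ones((250, 1)), [sm], lambdas=[lam])
            edfs.append(fit.edf[sm.name])
        assert all(a >= b - 1e-8 for a, b in zip(edfs[:-1], edfs[1:]))

    def test_reml_selection_near_best_on_grid(self):
        """REML's integrated squared error is within 2x of the best fixed
        lambda on a grid, for y = sin(x) + noise."""
        rng = np.random.default_rng(5)
        n = 400
        x = rng.uniform(0, 1, n)
        truth = np.sin(2 * np.pi * x)
        y = truth + rng.normal(0, 0.4, n)
        g = np.linspace(0.02, 0.98, 200)
        tg = np.sin(2 * np.pi * g)

        def ise(lam):
            sm = build_univariate_basis(x, k=12)
            fit = fit_penalized(y, np.ones((n, 1)), [sm],
                                lambdas=None if lam is None else [lam])
            est = fit.beta[0] + sm.evaluate(g)
            return np.mean((est - tg) ** 2)

        best = min(ise(lam) for lam in 10.0 ** np.arange(-4, 6))
        assert ise(None) <= 2.0 * best + 1e-12

    def test_saturated_r2_bounds_penalized_r2(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.uniform(0, 1, n)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, n)
        sm_sat = build_univariate_basis(x, k=12)
        r2_sat = fit_penalized(y, np.ones((n, 1)), [sm_sat], lambdas=[1e-10]).r2
        for lam in [1.0, 100.0, 1e4]:
            sm = build_univariate_basis(x, k=12)
            assert r2_sat >= fit_penalized(y, np.ones((n, 1)), [sm],
                                           lambdas=[lam]).r2 - 1e-10

    def test_rank_deficient_design_names_columns(self):
        n = 60
        a = rng0.normal(size=n)
        X = np.column_stack([np.ones(n), a, 2 * a])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_penalized(rng0.normal(size=n), X, [],
                          param_names=["intercept", "a", "twice_a"])

    def test_non_finite_response_rejected(self):
        y = np.array([1.0, np.nan, 2.0])
        with pytest.raises(ValueError, match="non-finite"):
            fit_penalized(y, np.ones((3, 1)), [])


class TestSmoothPValue:
    def _fit(self, signal=1.0, n=600, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, n)
        y = signal * np.sin(2 * np.pi * x) + rng.normal(0, 0.5, n)
        sm = build_univariate_basis(x, k=10)
        return fit_penalized(y, np.ones((n, 1)), [sm]), sm, x, y

    def test_zero_coefficients_give_p_one(self):
        fit, sm, _, _ = self._fit(signal=1.0)
        fit.beta[fit.slices[sm.name]] = 0.0
        assert smooth_pvalue(fit, sm.name) == pytest.approx(1.0)

    def test_strong_signal_agrees_with_permutation_null(self):
        """Wald p under strong signal is tiny; permuting the covariate
        destroys it (independent check of the test's calibration)."""
        fit, sm, x, y = self._fit(signal=1.0, n=800)
        assert smooth_pvalue(fit, sm.name) < 1e-3
        rng = np.random.default_rng(9)
        perm_ps = []
        for _ in range(20):
            xp = rng.permutation(x)
            smp = build_univariate_basis(xp, k=10)
            fp = fit_penalized(y, np.ones((len(y), 1)), [smp])
            perm_ps.append(smooth_pvalue(fp, smp.name))
        # under the permutation null, small p-values are rare
        assert np.mean(np.asarray(perm_ps) < 0.05) <= 0.25

    def test_p_in_unit_interval(self):
        for seed in range(5):
            fit, sm, _, _ = self._fit(signal=0.0, seed=seed)
            assert 0.0 <= smooth_pvalue(fit, sm.name) <= 1.0
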