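import warnings

import numpy as np
import pytest
from scipy.interpolate import CubicSpline, make_smoothing_spline

import shadowspline as ss
from shadowspline import error_models as em
from shadowspline.shadows import ShadowPairs


class TestFitShadowLinear:
    def test_noiseless_line_is_exact(self):
        n = np.arange(10, 110, 10, dtype=float)
        pairs = ShadowPairs(n=n, s=2 + 0.5 * n)
        fit = em.fit_shadow_linear(pairs)
        assert fit.intercept == pytest.approx(2.0, abs=1e-8)
        assert fit.slope == pytest.approx(0.5, abs=1e-8)
        assert fit.converged

    def test_flat_data(self):
        n = np.arange(1, 11, dtype=float)
        pairs = ShadowPairs(n=n, s=np.full(10, 7.0))
        fit = em.fit_shadow_linear(pairs)
        assert fit.intercept == pytest.approx(7.0, abs=1e-8)
        assert fit.slope == pytest.approx(0.0, abs=1e-8)

    def test_recovery_agrees_with_ols_under_symmetric_noise(self):
        rng = np.random.default_rng(12)
        n = rng.integers(100, 10001, 1000).astype(float)
        s = np.clip(0.25 * n + rng.normal(0, 5, 1000), 0, None)
        pairs = ShadowPairs(n=n, s=s)
        fit = em.fit_shadow_linear(pairs)
        ols_slope = np.polyfit(pairs.n, pairs.s, 1)[0]
        assert fit.slope == pytest.approx(0.25, abs=0.01)
        assert fit.slope == pytest.approx(ols_slope, abs=0.002)

    def test_degenerate_design_rejected(self):
        pairs = ShadowPairs(n=[5, 5, 5], s=[1, 2, 3])
        with pytest.raises(ValueError, match="degenerate"):
            em.fit_shadow_linear(pairs)

    def test_too_few_observations_rejected(self):
        pairs = ShadowPairs(n=[5, 6], s=[1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            em.fit_shadow_linear(pairs)


class TestSrer:
    @pytest.mark.parametrize(
        "slope,expected",
        [(0.0, 0.0), (1.0, 0.5), (0.25, 0.2), (-0.3, 0.0)],
    )
    def test_slope_to_rate(self, slope, expected):
        assert em.srer(em.LinearFit(0.0, slope)) == pytest.approx(expected)


class TestCubicSpline:
    def test_reproduces_affine_data_for_any_lambda(self):
        n = np.arange(1, 21, dtype=float)
        pairs = ShadowPairs(n=n, s=3 + 0.7 * n)
        for lam in (0.0, 1.0, 1e6):
            curve = em.fit_cubic_spline(pairs, em.SplineConfig(lam=lam))
            np.testing.assert_allclose(curve.fitted, 3 + 0.7 * n, rtol=1e-8)

    def test_huge_lambda_reaches_least_squares_line(self):
        rng = np.random.default_rng(2)
        n = np.sort(rng.choice(np.arange(10, 5000), 200, replace=False)).astype(float)
        s = np.clip(0.2 * n + rng.normal(0, 20, 200), 0, None)
        pairs = ShadowPairs(n=n, s=s)
        curve = em.fit_cubic_spline(pairs, em.SplineConfig(lam=1e12 * np.ptp(n)))
        b, a = np.polyfit(n, s, 1)
        line = a + b * n
        assert np.max(np.abs(curve.fitted - line)) <= 1e-6 * np.max(np.abs(line))

    def test_lambda_zero_interpolates(self):
        rng = np.random.default_rng(3)
        n = np.sort(rng.choice(np.arange(1, 500), 10, replace=False)).astype(float)
        s = rng.uniform(0, 100, 10)
        pairs = ShadowPairs(n=n, s=s)
        curve = em.fit_cubic_spline(pairs, em.SplineConfig(lam=0.0))
        np.testing.assert_allclose(curve.fitted, s, atol=1e-10)
        # off-knot values follow the independently built natural interpolant
        oracle = CubicSpline(n, s, bc_type="natural")
        mid = 0.5 * (n[:-1] + n[1:])
        np.testing.assert_allclose(curve(mid), oracle(mid), rtol=1e-10, atol=1e-10)

    def test_matches_scipy_smoothing_spline_at_moderate_lambda(self):
        rng = np.random.default_rng(4)
        n = np.sort(rng.choice(np.arange(1, 2000), 150, replace=False)).astype(float)
        s = np.clip(0.1 * n + 30 * np.sin(n / 200) + rng.normal(0, 5, 150), 0, None)
        pairs = ShadowPairs(n=n, s=s)
        for lam in (1.0, 100.0, 1e4):
            curve = em.fit_cubic_spline(pairs, em.SplineConfig(lam=lam))
            oracle = make_smoothing_spline(n, s, lam=lam)
            np.testing.assert_allclose(curve.fitted, oracle(n), rtol=1e-6, atol=1e-8)

    def test_ties_are_collapsed_with_weights(self):
        # two observations at n=10 with mean 5 must pull the fit like one
        # point of double weight at s=5
        pairs = ShadowPairs(n=[10, 10, 20, 30, 40, 50], s=[4, 6, 8, 12, 16, 20])
        curve = em.fit_cubic_spline(pairs, em.SplineConfig(lam=1e9))
        assert curve.fitted.shape == (6,)
        assert curve.fitted[0] == pytest.approx(curve.fitted[1])

    def test_too_few_distinct_points_rejected(self):
        pairs = ShadowPairs(n=[10, 10, 20, 30], s=[1, 2, 3, 4])
        with pytest.raises(ValueError, match="distinct"):
            em.fit_cubic_spline(pairs)

    def test_evaluation_outside_range_rejected(self):
        pairs = ShadowPairs(n=[10, 20, 30, 40, 50], s=[1, 2, 3, 4, 5])
        curve = em.fit_cubic_spline(pairs, em.SplineConfig(lam=1.0))
        with pytest.raises(ValueError, match="outside"):
            curve(55.0)


class TestRobustSpline:
    def test_equals_cubic_when_residuals_vanish(self):
        """Zero residuals floor all weights equally, so the reweighted fit
        is a fixed point: affine data (exact at any lambda) and noiseless
        interpolation (lambda 0) give identical cubic and robust fits."""
        n = np.arange(5, 305, 5, dtype=float)
        line = ShadowPairs(n=n, s=2 + 0.4 * n)
        for lam in (0.0, 10.0, 1e6):
            cubic = em.fit_cubic_spline(line, em.SplineConfig(lam=lam))
            robust = em.fit_robust_spline(line, em.SplineConfig(method="robust", lam=lam))
            np.testing.assert_allclose(robust.fitted, cubic.fitted, rtol=1e-6, atol=1e-8)
            assert robust.converged
        pairs, _ = ss.generate_nonlinear_pairs("saturating", noise=0.0, m=60, seed=5)
        cubic = em.fit_cubic_spline(pairs, em.SplineConfig(lam=0.0))
        robust = em.fit_robust_spline(pairs, em.SplineConfig(method="robust", lam=0.0))
        np.testing.assert_allclose(robust.fitted, cubic.fitted, rtol=1e-6, atol=1e-8)

    def test_constant_shadow_counts_fit_constant(self):
        pairs = ShadowPairs(n=[10, 20, 30, 40, 50], s=np.full(5, 9.0))
        robust = em.fit_robust_spline(pairs)
        np.testing.assert_allclose(robust.fitted, 9.0, atol=1e-8)

    def test_downweights_gross_outlier(self):
        rng = np.random.default_rng(5)
        n = np.sort(rng.choice(np.arange(10, 2000), 200, replace=False)).astype(float)
        s_clean = np.clip(0.2 * n + 30 * np.sin(n / 300) + rng.normal(0, 4, 200), 0, None)
        k = 100
        s_bad = s_clean.copy()
        s_bad[k] *= 20
        clean_fit = em.fit_cubic_spline(ShadowPairs(n=n, s=s_clean))
        contaminated = em.fit_cubic_spline(ShadowPairs(n=n, s=s_bad))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            robust = em.fit_robust_spline(ShadowPairs(n=n, s=s_bad))
        mask = np.ones(200, bool)
        mask[k] = False
        dev_cubic = np.sum((contaminated.fitted[mask] - clean_fit.fitted[mask]) ** 2)
        dev_robust = np.sum((robust.fitted[mask] - clean_fit.fitted[mask]) ** 2)
        assert dev_robust < dev_cubic


def curve_from_values(n, fitted):
    n = np.asarray(n, float)
    fitted = np.asarray(fitted, float)
    return em.FittedCurve("cubic", 0.0, 0.0, n, fitted, fitted)


class TestPerReadErrorRate:
    def test_hand_computed_cumulative_ratio(self):
        pairs = ShadowPairs(n=[10, 20, 30], s=[0, 0, 0])
        curve = curve_from_values([10, 20, 30], [1.0, 2.0, 3.0])
        assert em.per_read_error_rate(curve, pairs, 30) == pytest.approx(6 / 66)
        assert em.per_read_error_rate(curve, pairs, 10) == pytest.approx(1 / 11)

    def test_zero_fitted_gives_zero(self):
        pairs = ShadowPairs(n=[10, 20, 30], s=[1, 2, 3])
        curve = curve_from_values([10, 20, 30], [0.0, 0.0, 0.0])
        for x in (10, 20, 30):
            assert em.per_read_error_rate(curve, pairs, x) == 0.0

    def test_fitted_equal_to_counts_gives_half(self):
        pairs = ShadowPairs(n=[10, 20, 30], s=[1, 2, 3])
        curve = curve_from_values([10, 20, 30], [10.0, 20.0, 30.0])
        for x in (10, 25, 30):
            assert em.per_read_error_rate(curve, pairs, x) == pytest.approx(0.5)

    def test_negative_fitted_values_clamped(self):
        pairs = ShadowPairs(n=[10, 20, 30], s=[1, 2, 3])
        curve = curve_from_values([10, 20, 30], [-5.0, 2.0, 3.0])
        assert em.per_read_error_rate(curve, pairs, 10) == 0.0

    def test_outside_range_rejected(self):
        pairs = ShadowPairs(n=[10, 20, 30], s=[1, 2, 3])
        curve = curve_from_values([10, 20, 30], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="outside"):
            em.per_read_error_rate(curve, pairs, 31)

    def test_always_a_proper_rate(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m = int(rng.integers(4, 50))
            n = np.sort(rng.choice(np.arange(1, 10000), m, replace=False)).astype(float)
            fitted = rng.normal(0, 50, m)
            pairs = ShadowPairs(n=n, s=np.clip(fitted, 0, None))
            curve = curve_from_values(n, fitted)
            x = float(rng.uniform(n[0], n[-1]))
            er = em.per_read_error_rate(curve, pairs, x)
            assert 0.0 <= er < 1.0


class TestSampleEer:
    def test_constant_rate_any_seed(self):
        pairs = ShadowPairs(n=[10, 20, 30, 40], s=[1, 2, 3, 4])
        curve = curve_from_values([10, 20, 30, 40], [10.0, 20.0, 30.0, 40.0])
        for seed in (0, 1, 99):
            eer, samples = em.sample_eer(curve, pairs, draws=100, rng=np.random.default_rng(seed))
            assert eer == pytest.approx(0.5)
            assert len(samples) == 100

    def test_single_draw_equals_that_rate(self):
        pairs = ShadowPairs(n=[10, 20, 30, 40], s=[1, 2, 3, 4])
        curve = curve_from_values([10, 20, 30, 40], [1.0, 2.0, 3.0, 4.0])
        eer, samples = em.sample_eer(curve, pairs, draws=1, rng=np.random.default_rng(3))
        x, er = samples[0]
        assert eer == pytest.approx(er)
        assert eer == pytest.approx(em.per_read_error_rate(curve, pairs, x))

    def test_median_close_to_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        n = np.sort(rng.choice(np.arange(50, 5000), 300, replace=False)).astype(float)
        s = np.clip(0.1 * n + rng.normal(0, 10, 300), 0, None)
        pairs = ShadowPairs(n=n, s=s)
        curve = em.fit_cubic_spline(pairs)
        eer, _ = em.sample_eer(curve, pairs, draws=1000, rng=np.random.default_rng(8))
        xs = np.arange(int(n[0]), int(n[-1]) + 1)
        exhaustive = np.median([em.per_read_error_rate(curve, pairs, x) for x in xs])
        assert eer == pytest.approx(exhaustive, abs=0.005)

    def test_observed_scheme_draws_observed_counts(self):
        pairs = ShadowPairs(n=[10, 20, 30, 40], s=[1, 2, 3, 4])
        curve = curve_from_values([10, 20, 30, 40], [1.0, 2.0, 3.0, 4.0])
        _, samples = em.sample_eer(
            curve, pairs, draws=50, rng=np.random.default_rng(0), scheme="observed"
        )
        assert set(x for x, _ in samples) <= {10.0, 20.0, 30.0, 40.0}

    def test_unknown_scheme_rejected(self):
        pairs = ShadowPairs(n=[10, 20, 30, 40], s=[1, 2, 3, 4])
        curve = curve_from_values([10, 20, 30, 40], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="scheme"):
            em.sample_eer(curve, pairs, draws=5, scheme="bogus")
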