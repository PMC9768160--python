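"""Statistical procedures: d', Weibull fit, OLS bootstrap, probit, RT summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from satnet.stats import (
    dprime,
    fit_weibull,
    neighborhood_rt_map,
    ols_slope_boot,
    probit_fit,
    rt_summaries,
    skewness_g1,
    weibull_pc,
)


class TestDprime:
    def test_chance_performance_is_zero(self):
        assert dprime(0.5, 0.5, 100) == 0.0

    def test_normal_quantile_value(self):
        # Phi^-1(0.84) - Phi^-1(0.16) ~ 1.989
        assert dprime(0.84, 0.16, 10_000) == pytest.approx(1.989, abs=1e-3)

    def test_perfect_accuracy_clamped_finite(self):
        d = dprime(1.0, 0.0, 500)
        expected = 2 * sps.norm.ppf(1 - 1 / 1000)
        assert d == pytest.approx(expected)
        assert np.isfinite(d)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            dprime(0.6, 0.4, 0)

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry(self, p):
        assert dprime(p, 1 - p, 1000) == pytest.approx(-dprime(1 - p, p, 1000), abs=1e-12)


class TestWeibull:
    C_GRID = np.array([3.2, 6.4, 12.8, 25.6, 51.2])

    def test_chance_level_at_zero_strength(self):
        for alpha, beta in [(15.0, 1.1), (6.0, 1.7), (0.3, 4.0)]:
            assert weibull_pc(np.array([0.0]), alpha, beta)[0] == 0.5

    @pytest.mark.parametrize("alpha,beta", [(15.0, 1.1), (6.0, 1.7)])
    def test_recovers_published_parameterizations_from_their_curves(self, alpha, beta):
        p = weibull_pc(self.C_GRID, alpha, beta)
        fit = fit_weibull(self.C_GRID, p)
        assert fit.alpha == pytest.approx(alpha, rel=1e-4)
        assert fit.beta == pytest.approx(beta, rel=1e-4)

    def test_recovery_under_binomial_noise(self):
        rng = np.random.default_rng(3)
        truth = weibull_pc(self.C_GRID, 12.5, 1.18)
        n = 2000
        noisy = rng.binomial(n, truth) / n
        fit = fit_weibull(self.C_GRID, noisy)
        assert fit.alpha == pytest.approx(12.5, rel=0.15)
        assert fit.beta == pytest.approx(1.18, rel=0.25)

    def test_scale_consistency(self):
        p = weibull_pc(self.C_GRID, 10.0, 1.3)
        f1 = fit_weibull(self.C_GRID, p)
        f2 = fit_weibull(self.C_GRID * 3.0, p)
        assert f2.alpha == pytest.approx(3.0 * f1.alpha, rel=1e-3)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-3)

    def test_needs_two_positive_strengths(self):
        with pytest.raises(ValueError):
            fit_weibull(np.array([0.0, 5.0]), np.array([0.5, 0.8]))


class TestOlsSlopeBoot:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = ols_slope_boot(x, 2.0 * x, n_boot=200, rng=0)
        assert res.slope == pytest.approx(2.0)
        assert res.ci_low == pytest.approx(2.0) and res.ci_high == pytest.approx(2.0)

    def test_hand_computed_normal_equations(self):
        # x=[0..4], y=[1,3,2,5,4]: slope 8/10, intercept 3 - 0.8*2
        res = ols_slope_boot(np.arange(5.0), np.array([1.0, 3.0, 2.0, 5.0, 4.0]), n_boot=100, rng=1)
        assert res.slope == pytest.approx(0.8)
        assert res.intercept == pytest.approx(1.4)

    def test_default_bootstrap_draws(self):
        import inspect

        assert inspect.signature(ols_slope_boot).parameters["n_boot"].default == 10_000

    def test_bootstrap_mean_tracks_slope(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 200)
        y = 3.0 * x + rng.normal(0, 0.5, 200)
        res = ols_slope_boot(x, y, n_boot=10_000, rng=2)
        assert res.bootstrap_mean == pytest.approx(res.slope, abs=3 * res.bootstrap_sd / 10)
        assert res.ci_low < res.slope < res.ci_high

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            ols_slope_boot(np.ones(5), np.arange(5.0), n_boot=10, rng=0)


class TestProbit:
    def test_null_covariate_gives_small_estimate(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 2000)
        x = rng.uniform(0, 1, 2000)
        est, t = probit_fit(y, x)
        assert abs(t) < 3.0

    def test_parameter_recovery(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 0.5, 3000)
        p = sps.norm.cdf(-1.5 + 7.0 * x)
        y = rng.random(3000) < p
        est, t = probit_fit(y.astype(float), x)
        assert est == pytest.approx(7.0, abs=1.5)
        assert t > 5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            probit_fit(np.ones(10), np.arange(10.0))


class TestRTSummaries:
    def test_identical_error_and_correct_lists_give_zero_difference(self):
        rts = np.array([300.0, 400.0, 500.0])
        s = rt_summaries(rts, rts, np.concatenate([rts, rts]))
        assert s.rt_diff_ec == 0.0

    def test_missing_errors_reported_absent(self):
        s = rt_summaries(np.array([300.0, 400.0]), np.array([]), np.array([300.0, 400.0]))
        assert s.rt_diff_ec is None

    def test_skewness_moment_arithmetic(self):
        # {1,2,3,4,10}: m2=10, m3=36 -> g1 = 36/10^1.5
        assert skewness_g1(np.array([1.0, 2.0, 3.0, 4.0, 10.0])) == pytest.approx(1.1384, abs=1e-4)
        assert skewness_g1(np.array([5.0, 5.0, 5.0])) == 0.0


class TestNeighborhoodMap:
    @staticmethod
    def _table(rng, n=4000, corner_slow=True):
        la = rng.uniform(0, 20, n)
        lb = rng.uniform(0, 20, n)
        correct = rng.random(n) < 0.7
        rt = rng.normal(500, 50, n)
        in_corner = (la < 8) & (lb < 8)
        # errors slower only in the low-input corner, faster elsewhere
        rt[~correct & in_corner] += 150 if corner_slow else -150
        rt[~correct & ~in_corner] -= 150
        return pd.DataFrame(
            {"lambda_A": la, "lambda_B": lb, "decided": True, "correct": correct, "rt_ms": rt}
        )

    def test_no_errors_reports_no_probes(self):
        df = pd.DataFrame(
            {"lambda_A": [1.0, 2.0], "lambda_B": [1.0, 2.0], "decided": [True, True],
             "correct": [True, True], "rt_ms": [400.0, 500.0]}
        )
        probes, width = neighborhood_rt_map(df, probes=10, rng=0)
        assert probes == [] and np.isnan(width)

    def test_sign_structure_recovered(self):
        rng = np.random.default_rng(12)
        df = self._table(rng)
        probes = np.array([[4.0, 4.0], [15.0, 15.0], [15.0, 4.0]])
        out, width = neighborhood_rt_map(df, probes=probes, rng=1)
        by_loc = {(p.lambda_A, p.lambda_B): p for p in out}
        assert not by_loc[(4.0, 4.0)].reverse  # errors slower in the corner
        assert by_loc[(15.0, 15.0)].reverse
        assert by_loc[(15.0, 4.0)].reverse
        assert 0 < width <= 2.5

    def test_probe_without_error_quota_unreported(self):
        rng = np.random.default_rng(13)
        df = self._table(rng, n=60)  # far too few errors anywhere
        out, _ = neighborhood_rt_map(df, probes=np.array([[10.0, 10.0]]), rng=2, min_errors=50)
        assert out == []
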