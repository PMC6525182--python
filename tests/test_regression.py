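"""Tests for OLS, allometry-form NLS, and SMA estimation."""

import numpy as np
import pytest
import statsmodels.api as sm

from rootallometry.allometry import DomainError
from rootallometry.regression import (
    AllometricCurve,
    fit_anatomy_allometry,
    nls_allometric_fit,
    ols_fit,
    sma_common_slope_test,
    sma_fit,
)

rng = np.random.default_rng(20240915)


class TestOLS:
    def test_exact_line(self):
        fit = ols_fit([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        fit = ols_fit([0, 1, 2, 3], [5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r2 == 0.0

    def test_near_noise_free_recovery(self):
        x = np.linspace(0.1, 1.2, 50)
        y = 0.43 * x - 0.016 + rng.normal(0, 1e-6, 50)
        fit = ols_fit(x, y)
        assert fit.slope == pytest.approx(0.43, abs=1e-3)
        assert fit.intercept == pytest.approx(-0.016, abs=1e-3)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            ols_fit([1.0, 1.0, 1.0], [1, 2, 3])

    def test_agrees_with_statsmodels(self):
        # independent route: same estimates, SEs and p-value from the
        # full regression machinery
        x = rng.uniform(0, 3, 40)
        y = 1.7 * x + 0.4 + rng.normal(0, 0.5, 40)
        mine = ols_fit(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert mine.slope == pytest.approx(ref.params[1], rel=1e-10)
        assert mine.intercept == pytest.approx(ref.params[0], rel=1e-10)
        assert mine.slope_se == pytest.approx(ref.bse[1], rel=1e-8)
        assert mine.intercept_se == pytest.approx(ref.bse[0], rel=1e-8)
        assert mine.p_slope == pytest.approx(ref.pvalues[1], rel=1e-6)
        assert mine.r2 == pytest.approx(ref.rsquared, rel=1e-10)


class TestAllometricCurve:
    def test_noise_free_recovery_to_1e6(self):
        x = np.linspace(0.1, 1.0, 10)
        y = (0.5 + 0.1 / x) ** 2 + 0.05
        fit = nls_allometric_fit(x, y)
        assert fit.converged and not fit.degenerate
        assert fit.a == pytest.approx(0.5, abs=1e-6)
        assert fit.b == pytest.approx(0.1, abs=1e-6)
        assert fit.d == pytest.approx(0.05, abs=1e-6)

    def test_negative_b_recovered_with_positive_a(self):
        x = np.linspace(0.2, 2.0, 30)
        y = (0.8 - 0.15 / x) ** 2 + 0.3
        fit = nls_allometric_fit(x, y)
        assert fit.a == pytest.approx(0.8, abs=1e-6)
        assert fit.b == pytest.approx(-0.15, abs=1e-6)

    def test_constant_response_degenerate(self):
        fit = nls_allometric_fit(np.linspace(0.1, 1, 12), np.full(12, 3.0))
        assert fit.degenerate
        assert fit.d == pytest.approx(3.0)

    def test_r2_decreases_with_noise(self):
        x = np.tile(np.linspace(0.1, 1.2, 40), 5)
        signal = (0.37 + 0.05 / x) ** 2 + 0.1
        r2s = []
        for sigma in (0.01, 0.05, 0.2):
            y = signal + np.random.default_rng(3).normal(0, sigma, x.size)
            r2s.append(nls_allometric_fit(x, y).r2)
        assert r2s[0] > r2s[1] > r2s[2]

    def test_r2_invariant_to_reordering(self):
        x = rng.uniform(0.1, 1.5, 60)
        y = (0.4 + 0.08 / x) ** 2 + rng.normal(0, 0.05, 60)
        perm = rng.permutation(60)
        assert nls_allometric_fit(x, y).r2 == pytest.approx(
            nls_allometric_fit(x[perm], y[perm]).r2, abs=1e-9
        )

    def test_b_frozen_at_zero_matches_intercept_only_fit(self):
        x = np.linspace(0.2, 2.0, 25)
        y = rng.normal(5.0, 1.0, 25)
        fit = AllometricCurve(fix_b=0.0).fit(x, y).result()
        assert fit.a**2 + fit.d == pytest.approx(y.mean(), abs=1e-8)

    def test_ridge_case_flagged_degenerate_but_at_optimum(self):
        # data whose best expanded-basis fit has negative curvature: the
        # in-family optimum sits on the b -> 0 boundary
        x = np.linspace(0.2, 2.0, 50)
        y = 1.0 - 0.2 / x**2 + rng.normal(0, 0.01, 50)
        fit = nls_allometric_fit(x, y)
        assert fit.degenerate
        assert fit.converged  # certificate against the boundary infimum

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            nls_allometric_fit([0.1, 0.2, 0.3], [1, 2, 3])


class TestSMA:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2, 3, 4])
        assert sma_fit(x, 2 * x).slope == pytest.approx(2.0)

    def test_symmetry_under_axis_swap(self):
        x = rng.uniform(0, 1, 30)
        y = 2 * x + rng.normal(0, 0.1, 30)
        assert sma_fit(x, y).slope == pytest.approx(1.0 / sma_fit(y, x).slope)

    def test_sign_follows_correlation(self):
        x = np.array([0.0, 1, 2, 3, 4])
        y = np.array([12.0, 9, 6, 3, 0])  # sd(y) = 3 sd(x), r = -1
        assert sma_fit(x, y).slope == pytest.approx(-3.0)

    def test_slope_squared_is_variance_ratio(self):
        x = rng.normal(0, 1.3, 50)
        y = rng.normal(0, 0.7, 50)
        fit = sma_fit(x, y)
        assert fit.slope**2 == pytest.approx(np.var(y, ddof=1) / np.var(x, ddof=1))

    def test_ci_brackets_slope(self):
        x = rng.uniform(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 0.05, 40)
        fit = sma_fit(x, y)
        assert fit.slope_ci_low < fit.slope < fit.slope_ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sma_fit([1, 1, 1], [1, 2, 3])


class TestCommonSlope:
    def test_identical_groups_give_zero_statistic(self):
        x = rng.uniform(0, 1, 30)
        y = 0.4 * x + rng.normal(0, 0.02, 30)
        res = sma_common_slope_test([(x, y), (x, y)])
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.9

    def test_same_line_not_significant(self):
        # one representative null draw; the statistic's null calibration
        # is checked separately via its chi-squared reference
        g = np.random.default_rng(12)
        groups = []
        for _ in range(2):
            x = g.uniform(0.1, 1.2, 60)
            groups.append((x, 0.43 * x - 0.016 + g.normal(0, 0.02, 60)))
        res = sma_common_slope_test(groups, seed=0)
        assert res.p_value > 0.05

    def test_distinct_slopes_detected(self):
        g = np.random.default_rng(5)
        x1 = g.uniform(0.1, 1.2, 500)
        x2 = g.uniform(0.1, 1.2, 500)
        groups = [
            (x1, 0.43 * x1 + g.normal(0, 0.02, 500)),
            (x2, 0.32 * x2 + g.normal(0, 0.02, 500)),
        ]
        res = sma_common_slope_test(groups)
        assert res.method == "chi2"
        assert res.p_value < 0.001

    def test_small_groups_use_permutation(self):
        g = np.random.default_rng(9)
        x = g.uniform(0, 1, 12)
        res = sma_common_slope_test(
            [(x, x + g.normal(0, 0.1, 12)), (x, x + g.normal(0, 0.1, 12))],
            n_permutations=199,
            seed=1,
        )
        assert res.method == "permutation"
        assert 0 < res.p_value <= 1

    def test_degenerate_group_named(self):
        with pytest.raises(ValueError, match="group 1"):
            sma_common_slope_test([([1, 2, 3], [1, 2, 3]), ([1, 1, 1], [1, 2, 3])])


class TestAnatomyAllometry:
    def test_noise_free_exact(self):
        x = np.linspace(0.1, 1.2, 30)
        params, fit = fit_anatomy_allometry(x, 0.43 * x - 0.016)
        assert params.k == pytest.approx(0.43, abs=1e-12)
        assert params.c == pytest.approx(-0.016, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_minimum_size_runs_with_wide_errors(self):
        x = np.array([0.1, 0.5, 1.0])
        params, fit = fit_anatomy_allometry(x, 0.4 * x + 0.01 + [0.01, -0.02, 0.01])
        assert fit.n == 3
        assert fit.slope_se > 0

    def test_recovers_truth_within_two_se(self, small_dataset):
        table, _, truth = small_dataset
        woody = table[table["growth_form"] == "woody"].dropna(subset=["tToS"])
        params, fit = fit_anatomy_allometry(woody["diameter"], woody["tToS"])
        assert abs(params.k - truth["groups"]["woody"]["k"]) < 2 * fit.slope_se

    def test_anatomically_impossible_slope_rejected(self):
        x = np.linspace(0.1, 1.0, 20)
        with pytest.raises(DomainError):
            fit_anatomy_allometry(x, 0.8 * x)  # k = 0.8 > 0.5
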