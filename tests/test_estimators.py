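"""MR estimators against hand computations and independent WLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrpath.estimators import (egger, ivw, mode_based, mvmr, wald_ratios,
                               weighted_median, _mode_core,
                               _weighted_median_core)
from mrpath.summary_data import AnalysisError

from conftest import make_harmonized


def random_h(rng, n=10, theta=0.3):
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sy = rng.uniform(0.005, 0.05, n)
    by = theta * bx + rng.normal(0, sy)
    return make_harmonized(bx, by, sy, sx=rng.uniform(0.005, 0.02, n))


class TestWaldRatios:
    def test_arithmetic_and_sign(self):
        r = wald_ratios(make_harmonized([0.1, -0.1], [0.05, 0.05], [0.1, 0.1]))
        np.testing.assert_allclose(r.theta, [0.5, -0.5])
        np.testing.assert_allclose(r.se, [1.0, 1.0])

    def test_zero_bx_dropped_with_warning(self):
        h = make_harmonized([0.1, 0.0], [0.05, 0.05], [0.1, 0.1])
        with pytest.warns(UserWarning, match="zero exposure beta"):
            r = wald_ratios(h)
        assert len(r.theta) == 1

    def test_all_zero_bx_is_error(self):
        with pytest.raises(AnalysisError):
            wald_ratios(make_harmonized([0.0, 0.0], [0.1, 0.1], [0.1, 0.1]))


class TestIvw:
    def test_hand_computed_two_snp_case(self):
        # weights (100, 100): estimate 0.25, fixed SE sqrt(1/200), Q = 0.5
        h = make_harmonized([0.1, 0.2], [0.02, 0.06], [0.01, 0.02])
        fit = ivw(h)
        assert fit.estimate == pytest.approx(0.25)
        assert fit.se == pytest.approx(np.sqrt(1 / 200))  # max(1, Q/df) = 1
        assert fit.Q == pytest.approx(0.5)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(5):
            h = random_h(rng)
            fit = ivw(h)
            res = sm.WLS(h.by, h.bx[:, None], weights=1 / h.sy**2).fit()
            assert fit.estimate == pytest.approx(res.params[0], abs=1e-10)

    def test_homogeneous_ratios_give_q_zero(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.03, 0.06, 0.12],
                            [0.01, 0.01, 0.01])
        fit = ivw(h)
        assert fit.estimate == pytest.approx(0.3)
        assert fit.Q == pytest.approx(0.0, abs=1e-20) and fit.I2 == 0.0

    def test_single_snp_reduces_to_wald_ratio(self):
        fit = ivw(make_harmonized([0.1], [0.05], [0.02]))
        assert fit.estimate == pytest.approx(0.5)
        assert fit.se == pytest.approx(0.2)
        assert fit.method == "IVW" and fit.n_snps == 1

    def test_equal_weight_case_is_plain_mean(self):
        # equal sy and equal |bx| -> unweighted mean of ratios
        h = make_harmonized([0.2, -0.2, 0.2], [0.02, 0.03, 0.07],
                            [0.01, 0.01, 0.01])
        fit = ivw(h)
        assert fit.estimate == pytest.approx(np.mean(h.by / h.bx))

    def test_random_effects_inflation_floor(self, rng):
        h = random_h(rng, n=15)
        fit = ivw(h)
        fixed_se = np.sum(h.bx**2 / h.sy**2) ** -0.5
        assert fit.se >= fixed_se - 1e-15


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.01 + 0.2 * bx
        fit = egger(make_harmonized(bx, by, [0.01] * 3))
        assert fit.estimate == pytest.approx(0.2, abs=1e-12)
        assert fit.egger_intercept == pytest.approx(0.01, abs=1e-12)
        assert fit.Q == pytest.approx(0.0, abs=1e-18)

    def test_no_pleiotropy_limit_zero_intercept(self):
        bx = np.array([0.1, 0.25, 0.4, 0.6])
        fit = egger(make_harmonized(bx, 0.37 * bx, [0.02] * 4))
        assert fit.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.estimate == pytest.approx(0.37, abs=1e-12)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(5):
            h = random_h(rng, n=8)
            sign = np.where(h.bx < 0, -1, 1)
            X = sm.add_constant(h.bx * sign)
            res = sm.WLS(h.by * sign, X, weights=1 / h.sy**2).fit()
            fit = egger(h)
            assert fit.estimate == pytest.approx(res.params[1], abs=1e-10)
            assert fit.egger_intercept == pytest.approx(res.params[0], abs=1e-10)

    def test_requires_three_snps(self):
        with pytest.raises(AnalysisError):
            egger(make_harmonized([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]))

    def test_collinear_bx_is_error(self):
        with pytest.raises(AnalysisError, match="zero variance|collinear"):
            egger(make_harmonized([0.2, 0.2, -0.2], [0.1, 0.1, -0.1],
                                  [0.01] * 3))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], [1.0, 1.0, 1.0])
        fit = weighted_median(h, n_boot=50, seed=0)
        assert fit.estimate == pytest.approx(0.2)

    def test_hand_interpolated_unequal_weights(self):
        # theta (0.1, 0.2, 0.4), weights (1, 1, 6):
        # cumulative midpoints (0.0625, 0.1875, 0.625) -> 0.2 + (0.3125/0.4375)*0.2
        est = _weighted_median_core(np.array([0.1, 0.2, 0.4]),
                                    np.array([1.0, 1.0, 6.0]))
        assert est == pytest.approx(0.34285714285, abs=1e-9)

    def test_identical_ratios_recovered_with_positive_se(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.05, 0.1, 0.2], [0.01] * 3)
        fit = weighted_median(h, n_boot=200, seed=1)
        assert fit.estimate == pytest.approx(0.5)
        assert fit.se > 0

    def test_matches_fine_grid_quantile_oracle(self, rng):
        for _ in range(5):
            h = random_h(rng, n=9)
            theta = h.by / h.bx
            w = (h.bx / h.sy) ** 2
            order = np.argsort(theta)
            th, wt = theta[order], w[order]
            cum = (np.cumsum(wt) - wt / 2) / wt.sum()
            grid = np.linspace(th[0], th[-1], 200_001)
            cdf = np.interp(grid, th, cum)
            oracle = grid[np.argmin(np.abs(cdf - 0.5))]
            fit = weighted_median(h, n_boot=10, seed=0)
            assert fit.estimate == pytest.approx(oracle, abs=2 * (th[-1] - th[0]) / 200_000)

    def test_within_ratio_range(self, rng):
        h = random_h(rng, n=12)
        fit = weighted_median(h, n_boot=10, seed=0)
        theta = h.by / h.bx
        assert theta.min() <= fit.estimate <= theta.max()

    def test_bootstrap_is_seeded(self):
        h = make_harmonized([0.1, 0.2, 0.3, 0.4], [0.02, 0.05, 0.05, 0.09],
                            [0.01] * 4)
        a = weighted_median(h, n_boot=100, seed=42)
        b = weighted_median(h, n_boot=100, seed=42)
        assert a.se == b.se


class TestModeBased:
    def test_point_mass_recovered(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], [0.01] * 3)
        fit = mode_based(h, n_boot=50, seed=0)
        assert fit.estimate == pytest.approx(0.2, abs=1e-9)

    def test_majority_cluster_wins(self, rng):
        # 7 ratios near 0.2, 3 near 1.0 -> mode near 0.2
        bx = np.full(10, 0.2)
        theta = np.concatenate([rng.normal(0.2, 0.01, 7), rng.normal(1.0, 0.01, 3)])
        h = make_harmonized(bx, theta * bx, [0.01] * 10)
        fit = mode_based(h, n_boot=20, seed=0)
        assert abs(fit.estimate - 0.2) < 0.05

    def test_grid_argmax_matches_kde_oracle(self, rng):
        for _ in range(5):
            h = random_h(rng, n=10)
            theta = h.by / h.bx
            w = (h.bx / h.sy) ** 2
            n = len(theta)
            mad = np.median(np.abs(theta - np.median(theta)))
            s = 0.9 * min(theta.std(ddof=1), 1.4826 * mad) * n ** -0.2
            grid = np.linspace(theta.min() - 3 * s, theta.max() + 3 * s, 40_001)
            dens = (w * np.exp(-0.5 * ((grid[:, None] - theta) / s) ** 2)).sum(axis=1)
            oracle = grid[np.argmax(dens)]
            fit = mode_based(h, n_boot=10, seed=0)
            span = grid[-1] - grid[0]
            assert fit.estimate == pytest.approx(oracle, abs=span / 1000)


class TestMvmr:
    def test_exact_plane_recovered(self):
        rng = np.random.default_rng(0)
        bx1 = rng.uniform(0.1, 0.5, 6)
        bx2 = rng.uniform(-0.3, 0.3, 6)
        by = 0.3 * bx1 + 0.5 * bx2
        fits = mvmr(bx1, bx2, by, np.full(6, 0.01))
        assert fits["exposure"].estimate == pytest.approx(0.3, abs=1e-12)
        assert fits["mediator"].estimate == pytest.approx(0.5, abs=1e-12)
        assert fits["exposure"].Q == pytest.approx(0.0, abs=1e-18)

    def test_zero_column_is_rank_error(self):
        with pytest.raises(AnalysisError, match="collinear"):
            mvmr(np.array([0.1, 0.2, 0.3]), np.zeros(3),
                 np.array([0.03, 0.06, 0.09]), np.full(3, 0.01))

    def test_matches_wls_oracle(self, rng):
        for _ in range(5):
            n = 10
            bx1 = rng.uniform(0.05, 0.4, n)
            bx2 = rng.normal(0, 0.2, n)
            sy = rng.uniform(0.005, 0.03, n)
            by = 0.25 * bx1 - 0.4 * bx2 + rng.normal(0, sy)
            fits = mvmr(bx1, bx2, by, sy)
            res = sm.WLS(by, np.column_stack([bx1, bx2]), weights=1 / sy**2).fit()
            assert fits["exposure"].estimate == pytest.approx(res.params[0], abs=1e-10)
            assert fits["mediator"].estimate == pytest.approx(res.params[1], abs=1e-10)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_sign_equivariance_of_all_estimators(seed):
    """Negating every outcome beta negates each point estimate, SEs unchanged."""
    rng = np.random.default_rng(seed)
    h = random_h(rng, n=8)
    neg = make_harmonized(h.bx, -h.by, h.sy, sx=h.sx)
    for est, kwargs, tol, se_rel in [
            (ivw, {}, 1e-12, 1e-12), (egger, {}, 1e-12, 1e-12),
            # bootstrap SEs only match in distribution, point estimates exactly
            (weighted_median, {"n_boot": 50, "seed": 5}, 1e-9, 0.8),
            # mode matches to grid resolution (mirrored grids can differ by a tie)
            (mode_based, {"n_boot": 20, "seed": 5}, None, 0.8)]:
        a, b = est(h, **kwargs), est(neg, **kwargs)
        if tol is None:
            theta = h.by / h.bx
            tol = 4 * (theta.max() - theta.min() + 1e-9) / 1999
        assert a.estimate == pytest.approx(-b.estimate, abs=tol), est.__name__
        assert a.se == pytest.approx(b.se, rel=se_rel), est.__name__


def test_ci_brackets_estimate_and_or_view_consistent(rng):
    fit = ivw(random_h(rng))
    assert fit.ci_low <= fit.estimate <= fit.ci_high
    orv = fit.odds_ratio()
    assert orv.or_low <= orv.or_ <= orv.or_high
    assert orv.or_ == pytest.approx(np.exp(fit.estimate))
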