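"""Unit and oracle tests for the shared regression machinery."""

import numpy as np
import pytest

from lichendry.errors import (
    BoundaryBreakWarning,
    InvalidInputError,
    NoBreakWarning,
    RankDeficientError,
    UndefinedStatisticError,
)
from lichendry.stats_core import (
    adjusted_r2,
    fit_polynomial_cubic,
    fit_random_intercept,
    fit_segmented_linear,
    fit_segmented_mixed,
    segmented_oracle_grid,
)


def _two_segment(x, bp, b0, s_left, s_right):
    return np.where(x <= bp, b0 + s_left * x, b0 + s_left * bp + s_right * (x - bp))


# --------------------------------------------------------------------------
# two-segment linear model


class TestSegmentedLinear:
    def test_exact_noiseless_segments(self):
        x = np.linspace(0, 10, 21)
        y = _two_segment(x, 5.0, 0.0, 1.0, 0.0)
        fit = fit_segmented_linear(x, y)
        assert fit.breakpoint == pytest.approx(5.0, abs=1e-6)
        assert fit.slope_left == pytest.approx(1.0, abs=1e-8)
        assert fit.slope_right == pytest.approx(0.0, abs=1e-8)
        assert fit.rss < 1e-16
        assert fit.ci_low <= fit.breakpoint <= fit.ci_high

    def test_continuity_at_break(self, rng):
        x = np.sort(rng.uniform(0, 10, 40))
        y = _two_segment(x, 4.0, 1.0, 2.0, -0.5) + rng.normal(0, 0.3, 40)
        fit = fit_segmented_linear(x, y)
        left = fit.intercept_left + fit.slope_left * fit.breakpoint
        right = fit.intercept_right + fit.slope_right * fit.breakpoint
        assert abs(left - right) < 1e-9

    @pytest.mark.parametrize("n", [12, 30, 60])
    def test_matches_grid_oracle_within_one_step(self, n):
        rng = np.random.default_rng(314 + n)
        for _ in range(10):
            x = np.sort(rng.uniform(0, 10, n))
            bp = rng.uniform(3, 7)
            y = _two_segment(x, bp, 2.0, 1.5, 0.2) + rng.normal(0, 0.5, n)
            it = fit_segmented_linear(x, y)
            gr = segmented_oracle_grid(x, y)
            step = (np.quantile(x, 0.95) - np.quantile(x, 0.05)) / 200
            assert abs(it.breakpoint - gr.breakpoint) <= step + 1e-12

    def test_single_line_no_break_warning(self):
        x = np.linspace(0, 10, 25)
        y = 1.0 + 2.0 * x
        with pytest.warns((NoBreakWarning, BoundaryBreakWarning)):
            fit = fit_segmented_linear(x, y)
        # either an unbounded Wald interval or one spanning most of x
        assert not np.isfinite(fit.se_breakpoint) or (fit.ci_high - fit.ci_low) > 0.5 * np.ptp(x)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_segmented_linear([1, 2, 3, 4, 5], [1, 2, 3, 2, 1])


class TestSegmentedOracle:
    def test_oracle_minimizes_rss_over_lattice(self, rng):
        x = np.sort(rng.uniform(0, 10, 30))
        y = _two_segment(x, 6.0, 0.0, 1.0, -1.0) + rng.normal(0, 0.4, 30)
        best = segmented_oracle_grid(x, y, n_grid=101)
        lo, hi = np.quantile(x, 0.05), np.quantile(x, 0.95)
        for c in np.linspace(lo, hi, 101):
            X = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            assert best.rss <= rss + 1e-9

    def test_exact_on_noiseless_segments(self):
        x = np.linspace(0, 10, 41)
        y = _two_segment(x, 5.0, 0.0, 1.0, 0.0)
        assert segmented_oracle_grid(x, y).breakpoint == pytest.approx(5.0, abs=0.05)


# --------------------------------------------------------------------------
# random-intercept REML


class TestRandomIntercept:
    def test_identical_groups_no_noise(self):
        x = np.tile(np.arange(10.0), 2)
        y = 2.0 + 3.0 * x
        g = np.repeat(["a", "b"], 10)
        fit = fit_random_intercept(x, y, g)
        assert fit.fixed_intercept == pytest.approx(2.0, abs=1e-8)
        assert fit.fixed_slope == pytest.approx(3.0, abs=1e-8)
        assert fit.sigma_between == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma_within == pytest.approx(0.0, abs=1e-6)

    def test_balanced_offsets_recovered_as_blups(self):
        x = np.tile(np.arange(12.0), 2)
        offs = {"lo": -1.0, "hi": 1.0}
        y = np.concatenate([5.0 + 0.7 * np.arange(12.0) + o for o in offs.values()])
        g = np.repeat(list(offs), 12)
        fit = fit_random_intercept(x, y, g)
        assert fit.fixed_slope == pytest.approx(0.7, abs=1e-6)
        for k, o in offs.items():
            assert fit.per_group_intercepts[k] == pytest.approx(o, abs=1e-3)

    def test_matches_statsmodels_reml(self, rng):
        """Independent cross-check against the established REML implementation."""
        sm = pytest.importorskip("statsmodels.api")
        n_g, n_per = 5, 10
        x = rng.uniform(0, 10, n_g * n_per)
        g = np.repeat(np.arange(n_g), n_per)
        u = rng.normal(0, 2.0, n_g)
        y = 1.0 + 0.5 * x + u[g] + rng.normal(0, 1.0, x.size)
        ours = fit_random_intercept(x, y, g)
        md = sm.MixedLM(y, np.column_stack([np.ones_like(x), x]), groups=g).fit(reml=True)
        assert ours.fixed_intercept == pytest.approx(md.fe_params[0], rel=1e-4)
        assert ours.fixed_slope == pytest.approx(md.fe_params[1], rel=1e-4)
        assert ours.sigma_between**2 == pytest.approx(float(np.asarray(md.cov_re)[0, 0]), rel=1e-2)
        assert ours.sigma_within**2 == pytest.approx(md.scale, rel=1e-2)

    def test_single_group_profile_degenerates_to_ols(self, rng):
        # internal machinery: with an intercept column the GLS estimate equals
        # OLS for any variance ratio, so one group must give the OLS line
        from lichendry.stats_core import _profile_reml

        x = rng.uniform(0, 10, 20)
        y = 2.0 + 0.3 * x + rng.normal(0, 1.0, 20)
        X = np.column_stack([np.ones_like(x), x])
        _, beta, *_ = _profile_reml(X, y, [np.arange(20)])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_variance_component_recovery(self):
        """Monte-Carlo: REML variance components near truth on average."""
        rng = np.random.default_rng(8)
        sb, sw = 5.0, 2.0
        est_b, est_w = [], []
        for _ in range(100):
            g = np.repeat(np.arange(4), 20)
            x = rng.uniform(0, 10, 80)
            y = 1.0 + 2.0 * x + rng.normal(0, sb, 4)[g] + rng.normal(0, sw, 80)
            fit = fit_random_intercept(x, y, g)
            est_b.append(fit.sigma_between)
            est_w.append(fit.sigma_within)
        assert np.mean(est_b) == pytest.approx(sb, rel=0.30)
        assert np.mean(est_w) == pytest.approx(sw, rel=0.30)

    def test_needs_two_groups(self):
        with pytest.raises(InvalidInputError):
            fit_random_intercept([1, 2, 3], [1, 2, 3], ["a", "a", "a"])


class TestSegmentedMixed:
    @staticmethod
    def _grouped_break(rng, bp=7.0, sb=3.0, sw=1.0, n_g=4, n_per=20):
        g = np.repeat(np.arange(n_g), n_per)
        x = rng.uniform(0, 15, n_g * n_per)
        y = _two_segment(x, bp, 1.0, 2.0, 0.0) + rng.normal(0, sb, n_g)[g] + rng.normal(0, sw, x.size)
        return x, y, g

    def test_noiseless_grouped_break(self):
        rng = np.random.default_rng(5)
        g = np.repeat(np.arange(3), 15)
        x = np.tile(np.linspace(0, 15, 15), 3)
        y = _two_segment(x, 7.0, 1.0, 2.0, 0.0) + np.array([-2.0, 0.0, 2.0])[g]
        fit = fit_segmented_mixed(x, y, g)
        assert fit.breakpoint == pytest.approx(7.0, abs=0.05)
        assert fit.slope_left == pytest.approx(2.0, abs=1e-2)
        assert fit.slope_right == pytest.approx(0.0, abs=1e-2)
        # with zero residual noise the profile is razor sharp; the CI can only
        # be trusted to the candidate-lattice resolution
        lo, hi = np.quantile(x, 0.05), np.quantile(x, 0.95)
        fine_step = 2 * (hi - lo) / 40 / 40
        assert fit.ci_low - fine_step <= 7.0 <= fit.ci_high + fine_step

    def test_grid_refinement_convergence(self):
        rng = np.random.default_rng(17)
        x, y, g = self._grouped_break(rng)
        coarse = fit_segmented_mixed(x, y, g, n_grid=21)
        fine = fit_segmented_mixed(x, y, g, n_grid=41)
        lo, hi = np.quantile(x, 0.05), np.quantile(x, 0.95)
        fine_step = (hi - lo) / 40
        assert abs(coarse.breakpoint - fine.breakpoint) <= 2 * fine_step


# --------------------------------------------------------------------------
# cubic polynomial and adjusted R^2


class TestPolynomialCubic:
    def test_exact_cubic_coefficients(self):
        x = np.linspace(-2, 4, 20)
        y = 1.0 + 2.0 * x - x**2 + 0.5 * x**3
        fit = fit_polynomial_cubic(x, y)
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0, -1.0, 0.5], atol=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_data(self):
        x = np.linspace(0, 5, 10)
        fit = fit_polynomial_cubic(x, np.full(10, 3.0))
        np.testing.assert_allclose(fit.coefficients, [3.0, 0, 0, 0], atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 2 - 0.5 * x + 0.1 * x**2 + 0.02 * x**3 + rng.normal(0, 0.5, 40)
        fit = fit_polynomial_cubic(x, y)
        V = np.vander(x, 4, increasing=True)
        beta = np.linalg.solve(V.T @ V, V.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-8, atol=1e-8)

    def test_repeated_x_rejected(self):
        with pytest.raises((InvalidInputError, RankDeficientError)):
            fit_polynomial_cubic(np.full(10, 2.0), np.arange(10.0))

    def test_band_widens_away_from_data_mass(self, rng):
        x = rng.uniform(0, 10, 50)
        y = x + rng.normal(0, 1, 50)
        grid, lo, hi = fit_polynomial_cubic(x, y).ci_band
        width = hi - lo
        assert width[0] > width[len(width) // 2]


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = np.arange(10.0)
        assert adjusted_r2(y, y, 2) == pytest.approx(1.0)

    def test_mean_predictor(self):
        y = np.arange(10.0)
        expected = 1.0 - (1.0 - 0.0) * 9 / 8
        assert adjusted_r2(y, np.full(10, y.mean()), 1) == pytest.approx(expected)

    def test_matches_hand_formula(self, rng):
        y = rng.normal(0, 1, 30)
        y_hat = y + rng.normal(0, 0.3, 30)
        r2 = 1 - ((y - y_hat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        expected = 1 - (1 - r2) * 29 / (30 - 3 - 1)
        assert adjusted_r2(y, y_hat, 3) == pytest.approx(expected)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            adjusted_r2(np.full(10, 2.0), np.full(10, 2.0), 1)
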