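"""Curve fitting, matrix-effect comparison and sensitivity limits."""

import numpy as np
import pytest

from allerquant.calibration import (
    RegressionFit,
    compare_matrix_effect,
    fit_curve,
    limits,
    precision_at_ldp,
)


def normal_equations_fit(x, y):
    """Independent brute-force OLS oracle: explicit normal-equation sums."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    b = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    a = y.mean() - b * x.mean()
    resid = y - (a + b * x)
    s = np.sqrt((resid**2).sum() / (n - 2))
    sd_b = s / np.sqrt(sxx)
    sd_a = s * np.sqrt(1.0 / n + x.mean() ** 2 / sxx)
    return a, b, sd_a, sd_b, s


class TestFitCurve:
    def test_exact_line(self):
        fit = fit_curve([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_point_hand_ols(self):
        """(0,0),(1,1),(2,1): b = 0.5, a = 1/6 by closed-form OLS."""
        fit = fit_curve([0, 1, 2], [0, 1, 1])
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(1.0 / 6.0)
        # residuals -1/6, +1/3, -1/6 -> S_y/x = sqrt(1/6)
        assert fit.residual_sd == pytest.approx(np.sqrt(1.0 / 6.0))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(4, 15)
            x = np.sort(rng.uniform(0, 50, n))
            x[1] = x[0] + 1.0  # ensure distinct levels
            y = 0.01 + 0.03 * x + rng.normal(0, 0.01, n)
            fit = fit_curve(x, y)
            a, b, sd_a, sd_b, s = normal_equations_fit(x, y)
            assert fit.slope == pytest.approx(b, rel=1e-10)
            assert fit.intercept == pytest.approx(a, rel=1e-10, abs=1e-12)
            assert fit.sd_intercept == pytest.approx(sd_a, rel=1e-10)
            assert fit.sd_slope == pytest.approx(sd_b, rel=1e-10)
            assert fit.residual_sd == pytest.approx(s, rel=1e-10)

    def test_range_limit_excludes_high_points(self):
        x = [0.5, 1, 1.5, 2, 3, 5, 10, 25, 50]
        y = [0.03 * v for v in x]
        y[-1] += 5.0  # gross deviation above the limit must not matter
        fit = fit_curve(x, y, range_limit=5.0)
        assert fit.range == (0.5, 5.0)
        assert fit.slope == pytest.approx(0.03)

    def test_identical_x_rejected(self):
        with pytest.raises(ValueError):
            fit_curve([1, 1, 1], [1, 2, 3])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_curve([0, 1], [0, 1])


class TestMatrixEffect:
    def test_identical_curves(self, mcffv_noiseless_fit):
        x = np.tile([0.5, 1, 1.5, 2, 3, 5], 3)
        rng = np.random.default_rng(0)
        y = 0.02 * x + rng.normal(0, 0.001, x.size)
        f1 = fit_curve(x, y)
        cmp_res = compare_matrix_effect(f1, f1)
        assert cmp_res.F_statistic == pytest.approx(1.0)
        assert cmp_res.variances_poolable
        assert cmp_res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp_res.slopes_differ is False
        assert cmp_res.degrees_of_freedom == 2 * x.size - 4

    def test_detects_known_attenuation(self):
        """A 0.7x slope change at low noise must be flagged."""
        rng = np.random.default_rng(1)
        x = np.tile([0.5, 1, 1.5, 2, 3, 5, 10, 25, 50], 3)
        y1 = 0.03 * x + rng.normal(0, 0.002, x.size)
        y2 = 0.021 * x + rng.normal(0, 0.002, x.size)
        cmp_res = compare_matrix_effect(fit_curve(x, y1), fit_curve(x, y2))
        assert cmp_res.variances_poolable
        assert cmp_res.slopes_differ is True

    def test_nonpoolable_has_no_t_branch(self):
        rng = np.random.default_rng(2)
        x = np.tile([1, 2, 3, 5, 10], 4)
        f1 = fit_curve(x, 0.03 * x + rng.normal(0, 0.0005, x.size))
        f2 = fit_curve(x, 0.03 * x + rng.normal(0, 0.05, x.size))
        cmp_res = compare_matrix_effect(f1, f2)
        assert not cmp_res.variances_poolable
        assert cmp_res.t_statistic is None
        assert cmp_res.slopes_differ is None


class TestLimits:
    def _fit(self, sd_intercept=0.01, slope=0.02, residual_sd=0.02):
        return RegressionFit(
            slope=slope, intercept=0.0, sd_slope=0.001, sd_intercept=sd_intercept,
            residual_sd=residual_sd, n=18, reps_per_point=3.0, r_squared=0.999,
            x_mean=2.2, y_mean=0.05, sxx=50.0, range=(0.5, 5.0), peptide_code="x",
        )

    def test_lod_loq_formulas(self):
        fit = self._fit(sd_intercept=0.01, slope=0.02)
        lims = limits(fit, "intercept_sd")
        assert lims.lod == pytest.approx(3 * 0.01 / 0.02)
        assert lims.loq == pytest.approx(10 * 0.01 / 0.02)

    def test_loq_lod_ratio_is_ten_thirds(self):
        for method, kwargs in [
            ("intercept_sd", {}),
            ("residual_sd", {}),
            ("ldp_sd", {"ldp_ratios": [0.01, 0.012, 0.009, 0.011, 0.0105]}),
        ]:
            lims = limits(self._fit(), method, **kwargs)
            assert lims.loq / lims.lod == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_zero_sd_gives_zero_limits(self):
        lims = limits(self._fit(sd_intercept=0.0), "intercept_sd")
        assert lims.lod == 0.0 and lims.loq == 0.0

    def test_monotone_in_sd_antitone_in_slope(self):
        base = limits(self._fit(sd_intercept=0.01, slope=0.02), "intercept_sd")
        more_sd = limits(self._fit(sd_intercept=0.02, slope=0.02), "intercept_sd")
        more_slope = limits(self._fit(sd_intercept=0.01, slope=0.04), "intercept_sd")
        assert more_sd.lod > base.lod
        assert more_slope.lod < base.lod

    def test_ldp_requires_five_replicates(self):
        with pytest.raises(ValueError, match="5 replicate"):
            limits(self._fit(), "ldp_sd", ldp_ratios=[0.01, 0.012])

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            limits(self._fit(slope=-0.01))

    def test_lod_matches_hand_computation_on_synthetic_fit(self):
        rng = np.random.default_rng(3)
        x = np.tile([0.5, 1, 1.5, 2, 3, 5], 3)
        y = 0.002 + 0.0212 * x + rng.normal(0, 0.003, x.size)
        fit = fit_curve(x, y)
        _, b, sd_a, _, _ = normal_equations_fit(x, y)
        assert limits(fit, "intercept_sd").lod == pytest.approx(3 * sd_a / b, rel=1e-10)


class TestPrecisionAtLDP:
    def test_equal_ratios_zero_cv(self):
        assert precision_at_ldp([0.5, 0.5, 0.5]) == 0.0

    def test_hand_value(self):
        # SD({1.0, 1.1}) = 0.1/sqrt(2), mean 1.05 -> 6.734%
        assert precision_at_ldp([1.0, 1.1]) == pytest.approx(6.7343, abs=1e-3)

    def test_recovers_generating_cv(self):
        rng = np.random.default_rng(4)
        vals = 0.02 * (1 + rng.normal(0, 0.12, 4000))
        assert precision_at_ldp(vals) == pytest.approx(12.0, abs=1.0)
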