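"""Calibration fitting, matrix-effect testing and LOD/LOQ estimation.

The analytical signal is the L/H peak-area ratio; calibration curves are
ordinary unweighted least-squares lines of ratio on spiked concentration
(fmol/µL), with replicate measurements entering as individual observations.
Matrix effects are assessed by comparing the slopes of the matrix-matched
(MMCC) and standard (SCC) curves: residual variances are first screened with a
one-tail Fisher–Snedecor F-test and, if poolable, the slopes are compared with
a pooled-variance Student t-test.

Detection and quantification limits follow the calibration approach,
LOD = 3·SD/b and LOQ = 10·SD/b, where SD is one of three estimates: the
standard deviation of the intercept (default), the residual standard
deviation, or the signal SD at the lowest detected point (LDP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SDMethod = Literal["intercept_sd", "residual_sd", "ldp_sd"]


@dataclass(frozen=True)
class RegressionFit:
    """OLS summary of one L/H-ratio-vs-concentration calibration line."""

    slope: float
    intercept: float
    sd_slope: float
    sd_intercept: float
    residual_sd: float
    n: int
    reps_per_point: float
    r_squared: float
    x_mean: float
    y_mean: float
    sxx: float
    range: tuple[float, float]
    peptide_code: str = ""

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a calibration fit needs at least 3 observations")
        if self.sxx <= 0:
            raise ValueError("calibration concentrations are all identical")


@dataclass(frozen=True)
class SlopeComparison:
    """Outcome of the MMCC-vs-SCC matrix-effect test."""

    F_statistic: float
    F_critical: float
    variances_poolable: bool
    t_statistic: float | None
    t_critical: float | None
    degrees_of_freedom: int | None
    slopes_differ: bool | None


@dataclass(frozen=True)
class SensitivityLimits:
    """LOD/LOQ for one marker, in peptide and (optionally) TAFP units."""

    method: SDMethod
    lod: float
    loq: float
    lod_tafp: float | None = None
    loq_tafp: float | None = None
    peptide_code: str = ""


def fit_curve(
    levels: Sequence[float],
    ratios: Sequence[float],
    range_limit: float | None = None,
    peptide_code: str = "",
) -> RegressionFit:
    """Unweighted OLS fit of L/H ratio on concentration.

    ``range_limit`` restricts the fit to calibration points at or below the
    given concentration — used to characterise the low range where the limits
    are computed. Replicates enter as individual observations, preserving
    degrees of freedom for the intercept SD.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape:
        raise ValueError("levels and ratios must have the same length")
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if range_limit is not None:
        inside = x <= range_limit
        x, y = x[inside], y[inside]
    if len(np.unique(x)) < 3:
        raise ValueError("at least 3 distinct calibration levels are required")
    if np.ptp(x) == 0:
        raise ValueError("calibration concentrations are all identical")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    sd_intercept, sd_slope = res.bse
    n = len(y)
    resid_sd = float(np.sqrt(res.ssr / (n - 2)))
    # R² as squared Pearson correlation of fitted vs observed
    r2 = float(np.corrcoef(res.fittedvalues, y)[0, 1] ** 2) if resid_sd > 0 else 1.0
    _, counts = np.unique(x, return_counts=True)
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        sd_slope=float(sd_slope),
        sd_intercept=float(sd_intercept),
        residual_sd=resid_sd,
        n=n,
        reps_per_point=float(counts.mean()),
        r_squared=r2,
        x_mean=float(x.mean()),
        y_mean=float(y.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        range=(float(x.min()), float(x.max())),
        peptide_code=peptide_code,
    )


def fit_from_table(
    ratio_table: pd.DataFrame,
    peptide_code: str,
    range_limit: float | None = None,
) -> RegressionFit:
    """Fit one marker's curve from a long-format ratio table."""
    df = ratio_table[
        (ratio_table["peptide_code"] == peptide_code) & (ratio_table["flag"] == "")
    ]
    return fit_curve(
        df["nominal_level"].to_numpy(),
        df["ratio"].to_numpy(),
        range_limit=range_limit,
        peptide_code=peptide_code,
    )


def compare_matrix_effect(
    mmcc: RegressionFit,
    scc: RegressionFit,
    alpha_F: float = 0.01,
    alpha_t: float = 0.05,
) -> SlopeComparison:
    """Test whether the matrix changes the calibration slope.

    The residual variances of the two lines are screened with a one-tail
    F-test (larger over smaller variance) at ``alpha_F``; only if they are not
    significantly different are they pooled (weighted by degrees of freedom)
    for the slope t-test at ``alpha_t``, with n1 + n2 − 4 degrees of freedom.
    Non-poolable variances leave the t-branch not applicable — no silent
    Welch-style fallback.
    """
    v1, v2 = mmcc.residual_sd**2, scc.residual_sd**2
    df1, df2 = mmcc.n - 2, scc.n - 2
    if v1 >= v2:
        F, fdfn, fdfd = (v1 / v2 if v2 > 0 else np.inf), df1, df2
    else:
        F, fdfn, fdfd = v2 / v1 if v1 > 0 else np.inf, df2, df1
    if v1 == v2:
        F = 1.0
    F_crit = float(stats.f.ppf(1 - alpha_F, fdfn, fdfd))
    poolable = F <= F_crit
    if not poolable:
        return SlopeComparison(
            F_statistic=float(F),
            F_critical=F_crit,
            variances_poolable=False,
            t_statistic=None,
            t_critical=None,
            degrees_of_freedom=None,
            slopes_differ=None,
        )
    dof = mmcc.n + scc.n - 4
    s2_pooled = (df1 * v1 + df2 * v2) / dof
    se = np.sqrt(s2_pooled * (1.0 / mmcc.sxx + 1.0 / scc.sxx))
    t = abs(mmcc.slope - scc.slope) / se if se > 0 else 0.0
    t_crit = float(stats.t.ppf(1 - alpha_t / 2, dof))
    return SlopeComparison(
        F_statistic=float(F),
        F_critical=F_crit,
        variances_poolable=True,
        t_statistic=float(t),
        t_critical=t_crit,
        degrees_of_freedom=dof,
        slopes_differ=bool(t > t_crit),
    )


def limits(
    fit: RegressionFit,
    method: SDMethod = "intercept_sd",
    ldp_ratios: Sequence[float] | None = None,
) -> SensitivityLimits:
    """LOD = 3·SD/b and LOQ = 10·SD/b for the chosen SD estimate."""
    if fit.slope <= 0:
        raise ValueError("slope must be positive to derive detection limits")
    if method == "intercept_sd":
        sd = fit.sd_intercept
    elif method == "residual_sd":
        sd = fit.residual_sd
    elif method == "ldp_sd":
        if ldp_ratios is None or len(ldp_ratios) < 5:
            raise ValueError("ldp_sd requires at least 5 replicate LDP ratios")
        sd = float(np.std(ldp_ratios, ddof=1))
    else:
        raise ValueError(f"unknown SD method: {method}")
    lod = 3.0 * sd / fit.slope
    loq = 10.0 * sd / fit.slope
    return SensitivityLimits(
        method=method, lod=lod, loq=loq, peptide_code=fit.peptide_code
    )


def precision_at_ldp(ldp_ratios: Sequence[float]) -> float:
    """CV% (100·SD/mean) of replicate ratios at the lowest detected point."""
    r = np.asarray(ldp_ratios, dtype=float)
    if len(r) < 2:
        raise ValueError("precision needs at least 2 replicates")
    return float(100.0 * np.std(r, ddof=1) / np.mean(r))
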