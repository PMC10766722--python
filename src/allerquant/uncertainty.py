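"""Five-contributor measurement-uncertainty budget (GUM-style).

The combined standard uncertainty of a determined content x0 sums, in
quadrature on the relative scale, five contributors:

1. method precision u_PR — SD over repeated determinations divided by √3
   (rectangular distribution), covering instrumental plus sample-preparation
   variability;
2. synthetic-peptide stock concentration u_SS — the manufacturer's relative
   concentration precision (conservatively 30%) divided by √3, entering as a
   pure relative term since the stock concentration itself cancels;
3. calibration regression u_RL — the standard interpolation uncertainty
   (S_y/x / b) · sqrt(1/p + 1/n + (ȳ0 − ȳ)² / (b² · Sxx));
4. parent-protein molar mass u_MM — half-range/√3 over known isoforms;
5. conversion factor u_CF — half-range/√3 over independent discovery samples.

u_x0 = x0 · sqrt((u_PR/x0)² + u_SS_rel² + (u_RL/x0)² + (u_MM/cMM)² + (u_CF/cCF)²)
and the expanded uncertainty is U = k·u_x0 with coverage factor k = 2 for an
approximate 95% level of confidence. Because the peptide→TAFP conversion is
linear, the relative budget is identical on either unit scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import RegressionFit
from .panel_io import AllergenEntry

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class UncertaintyBudget:
    """The five standard-uncertainty contributors for one determined content."""

    x0: float
    u_PR: float
    u_SS_rel: float
    u_RL: float
    u_MM: float
    u_CF: float
    cMM: float
    cCF: float
    u_x0: float
    U_x0: float
    k: float

    @property
    def relative_contributions(self) -> dict[str, float]:
        """Per-contributor relative standard uncertainties u_i,rel."""
        return {
            "PR": self.u_PR / self.x0,
            "SS": self.u_SS_rel,
            "RL": self.u_RL / self.x0,
            "MM": self.u_MM / self.cMM,
            "CF": self.u_CF / self.cCF,
        }


def u_precision(observations: Sequence[float]) -> float:
    """SD of repeated determinations divided by √3 (rectangular assumption)."""
    obs = np.asarray(observations, dtype=float)
    if obs.size < 2:
        raise ValueError("precision contribution needs >= 2 observations")
    return float(np.std(obs, ddof=1) / SQRT3)


def u_stock(rel: float = 0.30) -> float:
    """Relative stock-solution contribution: rel/√3."""
    if rel < 0:
        raise ValueError("relative precision must be nonnegative")
    return rel / SQRT3


def u_regression(fit: RegressionFit, p: int, y0_mean: float) -> float:
    """Interpolation uncertainty of the calibration line, in fmol/µL."""
    if fit.slope == 0:
        raise ValueError("slope must be nonzero")
    if p < 1:
        raise ValueError("p must be >= 1")
    return (fit.residual_sd / fit.slope) * math.sqrt(
        1.0 / p
        + 1.0 / fit.n
        + (y0_mean - fit.y_mean) ** 2 / (fit.slope**2 * fit.sxx)
    )


def combine(
    x0: float,
    u_PR: float,
    u_SS_rel: float,
    u_RL: float,
    entry: AllergenEntry,
) -> float:
    """Root-sum-square combination of the five relative terms, scaled by x0."""
    if x0 <= 0:
        raise ValueError("cannot combine an uncertainty budget below LOQ (x0 <= 0)")
    rel_sq = (
        (u_PR / x0) ** 2
        + u_SS_rel**2
        + (u_RL / x0) ** 2
        + (entry.u_MM / entry.cMM) ** 2
        + (entry.u_CF / entry.cCF) ** 2
    )
    return x0 * math.sqrt(rel_sq)


def expand(u_x0: float, k: float = 2.0) -> float:
    """Expanded uncertainty U = k·u for an approximate 95% level at k = 2."""
    return k * u_x0


def build_budget(
    x0: float,
    observations: Sequence[float],
    fit: RegressionFit,
    y0_mean: float,
    entry: AllergenEntry,
    stock_rel: float = 0.30,
    k: float = 2.0,
) -> UncertaintyBudget:
    """Assemble the full budget for one determined peptide content."""
    upr = u_precision(observations)
    uss = u_stock(stock_rel)
    url = u_regression(fit, p=len(observations), y0_mean=y0_mean)
    u = combine(x0, upr, uss, url, entry)
    return UncertaintyBudget(
        x0=x0,
        u_PR=upr,
        u_SS_rel=uss,
        u_RL=url,
        u_MM=entry.u_MM,
        u_CF=entry.u_CF,
        cMM=entry.cMM,
        cCF=entry.cCF,
        u_x0=u,
        U_x0=expand(u, k),
        k=k,
    )


def format_result(value: float, U: float, k: float = 2.0) -> str:
    """Render "value ± U (k=...)" with U to 2 significant figures."""
    if U <= 0:
        return f"{value:g} ± 0 (k={k:g})"
    exp = math.floor(math.log10(abs(U)))
    digits = max(0, 1 - exp)
    return f"{round(value, digits):.{digits}f} ± {round(U, digits):.{digits}f} (k={k:g})"
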