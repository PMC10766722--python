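"""Repeatability, intermediate precision, variance components and recovery.

Repeatability is assessed on a one-day design of b biological (independently
prepared) samples × t technical (instrumental) replicates. A one-way ANOVA at
95% confidence first checks that the biological replicates may be pooled; the
total variance is then decomposed by the method of moments (expected mean
squares) into instrumental-analysis (IA) and sample-preparation (SP)
components, reported as relative weights of the total.

Intermediate precision adds day (DA) and analyst (A) factors: days and
analysts are crossed, samples nested within each day × analyst cell. Expected
mean squares give method-of-moments estimates of σ²_SP (residual), σ²_DA and
σ²_A; negative estimates are truncated to zero before weights are formed,
which is standard practice for balanced designs. Factors absent from the
design are reported as "nt" (not tested).

Recovery is the percent ratio of the contents determined in spiked-before vs
spiked-after samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantification import QuantResult


@dataclass(frozen=True)
class PrecisionResult:
    """Total CV% plus per-factor variance components for one ICB level."""

    level: float
    total_cv: float
    components: dict[str, tuple[float, float | None]]  # factor -> (var, weight %)
    anova_poolable: bool
    n_bio: int
    n_tech: int
    n_days: int = 1
    n_analysts: int = 1

    def weight(self, factor: str) -> float | None:
        return self.components[factor][1]


@dataclass(frozen=True)
class RecoveryResult:
    allergen: str
    qtm_code: str
    recovery_percent: float
    sb_value: float
    sa_value: float


def poolability_anova(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> tuple[bool, float, float]:
    """One-way ANOVA across replicate groups; poolable iff p >= alpha.

    Returns (poolable, F statistic, p value).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    F, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return bool(p >= alpha), float(F), float(p)


def _one_way_ms(df: pd.DataFrame, group_col: str, value_col: str) -> tuple[float, float, float]:
    """Between- and within-group mean squares plus per-group count (balanced)."""
    groups = [g[value_col].to_numpy(dtype=float) for _, g in df.groupby(group_col)]
    counts = {len(g) for g in groups}
    if len(counts) != 1:
        raise ValueError("unbalanced design")
    n = counts.pop()
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ms_between = n * sum((g.mean() - grand) ** 2 for g in groups) / (k - 1)
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / (k * (n - 1))
    return float(ms_between), float(ms_within), float(n)


def repeatability(
    data: pd.DataFrame,
    value_col: str = "value",
    bio_col: str = "biological_rep",
    level: float = float("nan"),
    alpha: float = 0.05,
) -> PrecisionResult:
    """Intra-day precision on a balanced bio × tech design.

    σ²_IA = MS_within; σ²_SP = max(0, (MS_between − MS_within)/t);
    total CV% = 100·sqrt(σ²_SP + σ²_IA)/grand mean; weights are each
    component's share of the summed variance.
    """
    df = data.dropna(subset=[value_col])
    counts = df.groupby(bio_col).size()
    if (counts != counts.iloc[0]).any():
        import warnings

        t = int(counts.min())
        warnings.warn(
            f"unbalanced design: truncating every sample to {t} technical reps",
            stacklevel=2,
        )
        df = df.groupby(bio_col, group_keys=False).head(t)
    b = df[bio_col].nunique()
    if b < 2:
        raise ValueError("need >= 2 biological replicates")
    ms_b, ms_w, t = _one_way_ms(df, bio_col, value_col)
    if t < 2:
        raise ValueError("need >= 2 technical replicates per sample")
    poolable, _, _ = poolability_anova(
        [g[value_col].to_numpy() for _, g in df.groupby(bio_col)], alpha=alpha
    )
    var_ia = ms_w
    var_sp = max(0.0, (ms_b - ms_w) / t)
    total = var_ia + var_sp
    grand = df[value_col].mean()
    weights = {
        "IA": (var_ia, 100.0 * var_ia / total if total > 0 else 0.0),
        "SP": (var_sp, 100.0 * var_sp / total if total > 0 else 0.0),
    }
    return PrecisionResult(
        level=level,
        total_cv=float(100.0 * np.sqrt(total) / grand) if grand != 0 else 0.0,
        components=weights,
        anova_poolable=poolable,
        n_bio=int(b),
        n_tech=int(t),
    )


def intermediate_precision(
    data: pd.DataFrame,
    value_col: str = "value",
    day_col: str = "day",
    analyst_col: str = "analyst",
    sample_col: str = "biological_rep",
    level: float = float("nan"),
    alpha: float = 0.05,
) -> PrecisionResult:
    """Inter-day / inter-analyst precision by EMS variance decomposition.

    The design is day crossed with analyst, independent samples nested within
    each cell; one determination per sample enters (technical replicates are
    averaged first when present). With d days, a analysts and n samples/cell:

        MS_day     estimates σ²_SP + a·n·σ²_DA
        MS_analyst estimates σ²_SP + d·n·σ²_A
        MS_resid   estimates σ²_SP

    A single-analyst design reports the analyst component "nt", mirroring
    validation tables where that factor was not tested.
    """
    df = (
        data.dropna(subset=[value_col])
        .groupby([day_col, analyst_col, sample_col], as_index=False)[value_col]
        .mean()
    )
    d = df[day_col].nunique()
    a = df[analyst_col].nunique()
    if d < 2:
        raise ValueError("intermediate precision needs >= 2 days")
    cell_counts = df.groupby([day_col, analyst_col]).size()
    if len(cell_counts) != d * a:
        raise ValueError("day x analyst grid is incomplete")
    n = int(cell_counts.min())
    if (cell_counts != n).any():
        import warnings

        warnings.warn(
            f"unbalanced cells: truncating to {n} samples per day x analyst cell",
            stacklevel=2,
        )
        df = df.groupby([day_col, analyst_col], group_keys=False).head(n)

    y = df[value_col].to_numpy(dtype=float)
    grand = y.mean()
    day_means = df.groupby(day_col)[value_col].mean()
    an_means = df.groupby(analyst_col)[value_col].mean()
    ss_day = a * n * ((day_means - grand) ** 2).sum()
    ss_an = d * n * ((an_means - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    df_day = d - 1
    df_an = a - 1 if a > 1 else 0
    df_res = len(y) - 1 - df_day - df_an
    ss_res = ss_tot - ss_day - ss_an
    ms_res = ss_res / df_res
    var_sp = max(0.0, float(ms_res))
    var_da = max(0.0, float((ss_day / df_day - ms_res) / (a * n)))

    components: dict[str, tuple[float, float | None]] = {}
    if a > 1:
        var_a = max(0.0, float((ss_an / df_an - ms_res) / (d * n)))
        total = var_sp + var_da + var_a
        components["A"] = (var_a, 100.0 * var_a / total if total > 0 else 0.0)
    else:
        var_a = 0.0
        total = var_sp + var_da
        components["A"] = (float("nan"), None)  # "nt": factor not tested
    components["SP"] = (var_sp, 100.0 * var_sp / total if total > 0 else 0.0)
    components["DA"] = (var_da, 100.0 * var_da / total if total > 0 else 0.0)

    groups = [g[value_col].to_numpy() for _, g in df.groupby([day_col, analyst_col])]
    poolable = (
        poolability_anova(groups, alpha=alpha)[0] if all(len(g) >= 2 for g in groups) else True
    )
    return PrecisionResult(
        level=level,
        total_cv=float(100.0 * np.sqrt(total) / grand) if grand != 0 else 0.0,
        components=components,
        anova_poolable=poolable,
        n_bio=n,
        n_tech=1,
        n_days=int(d),
        n_analysts=int(a),
    )


def stability_test(
    data: pd.DataFrame,
    value_col: str = "value",
    day_col: str = "day",
    alpha: float = 0.05,
) -> tuple[bool, dict[str, float]]:
    """Short-term sample stability: day-0 mean vs each later day by t-test.

    Returns (stable, {day: p-value}); stable iff no comparison is significant
    at ``alpha``. Each day needs >= 2 technical replicates.
    """
    days = sorted(data[day_col].unique())
    if len(days) < 2:
        raise ValueError("need >= 2 days")
    ref = data.loc[data[day_col] == days[0], value_col].to_numpy(dtype=float)
    if len(ref) < 2:
        raise ValueError("need >= 2 replicates per day")
    pvals: dict[str, float] = {}
    for day in days[1:]:
        cur = data.loc[data[day_col] == day, value_col].to_numpy(dtype=float)
        if len(cur) < 2:
            raise ValueError("need >= 2 replicates per day")
        _, p = stats.ttest_ind(ref, cur)
        pvals[str(day)] = float(p)
    return all(p >= alpha for p in pvals.values()), pvals


def recovery(sb: QuantResult, sa: QuantResult, qtm_code: str = "") -> RecoveryResult:
    """Method recovery: 100 × (spiked-before content)/(spiked-after content)."""
    if not (sb.quantifiable and sa.quantifiable):
        raise ValueError("both SB and SA must be quantifiable (>= LOQ)")
    assert sb.x0_tafp is not None and sa.x0_tafp is not None
    return RecoveryResult(
        allergen=sa.allergen_name,
        qtm_code=qtm_code,
        recovery_percent=100.0 * sb.x0_tafp / sa.x0_tafp,
        sb_value=sb.x0_tafp,
        sa_value=sa.x0_tafp,
    )
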