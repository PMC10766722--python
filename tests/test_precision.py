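"""ANOVA poolability, variance components, stability and recovery."""

import numpy as np
import pandas as pd
import pytest

from allerquant.precision import (
    intermediate_precision,
    poolability_anova,
    recovery,
    repeatability,
    stability_test,
)
from allerquant.quantification import QuantResult


def _repeat_df(rng, b=3, t=3, mean=10.0, sd_sp=0.0, sd_ia=0.1):
    rows = []
    for i in range(b):
        bio_mean = mean + (rng.normal(0, sd_sp) if sd_sp else 0.0)
        for j in range(t):
            rows.append(
                dict(biological_rep=f"b{i}", technical_rep=f"t{j}",
                     value=bio_mean + rng.normal(0, sd_ia))
            )
    return pd.DataFrame(rows)


class TestPoolability:
    def test_same_means_poolable(self):
        rng = np.random.default_rng(0)
        groups = [10 + rng.normal(0, 0.1, 5) for _ in range(3)]
        poolable, _, p = poolability_anova(groups)
        assert poolable and p >= 0.05

    def test_large_shift_not_poolable(self):
        rng = np.random.default_rng(1)
        groups = [10 + rng.normal(0, 0.1, 5) for _ in range(2)]
        groups.append(11.0 + rng.normal(0, 0.1, 5))  # 10 within-SDs away
        poolable, _, _ = poolability_anova(groups)
        assert not poolable

    def test_singleton_groups_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            poolability_anova([[1.0], [2.0]])


class TestRepeatability:
    def test_all_equal_zero_cv(self):
        df = _repeat_df(np.random.default_rng(2), sd_sp=0, sd_ia=0)
        res = repeatability(df)
        assert res.total_cv == 0.0

    def test_no_between_variance_gives_small_sp_weight(self):
        rng = np.random.default_rng(3)
        weights = []
        for _ in range(100):
            res = repeatability(_repeat_df(rng, sd_sp=0.0, sd_ia=0.1))
            weights.append(res.weight("SP"))
        # truncation at zero biases upward slightly; stays a minor share
        assert np.mean(weights) < 25.0

    def test_three_to_one_variance_ratio(self):
        """sigma_SP^2 = 3 sigma_IA^2: mean variance components give ~75/25.

        The method-of-moments components are unbiased, so weights formed from
        the across-seed mean variances recover the generating split (per-seed
        weights are skewed at b = 3 by the 2-df between-sample mean square).
        """
        rng = np.random.default_rng(4)
        sp_v, ia_v = [], []
        for _ in range(300):
            df = _repeat_df(rng, b=3, t=3, sd_sp=np.sqrt(3) * 0.1, sd_ia=0.1)
            res = repeatability(df)
            sp_v.append(res.components["SP"][0])
            ia_v.append(res.components["IA"][0])
        weight = 100 * np.mean(sp_v) / (np.mean(sp_v) + np.mean(ia_v))
        assert weight == pytest.approx(75.0, abs=5.0)

    def test_weights_sum_to_100(self):
        df = _repeat_df(np.random.default_rng(5), sd_sp=0.2, sd_ia=0.1)
        res = repeatability(df)
        assert res.weight("SP") + res.weight("IA") == pytest.approx(100.0)

    def test_scale_invariance_of_weights(self):
        df = _repeat_df(np.random.default_rng(6), sd_sp=0.2, sd_ia=0.1)
        res1 = repeatability(df)
        df2 = df.assign(value=df.value * 37.0)
        res2 = repeatability(df2)
        assert res1.weight("SP") == pytest.approx(res2.weight("SP"), rel=1e-9)
        assert res1.total_cv == pytest.approx(res2.total_cv, rel=1e-9)

    def test_unbalanced_truncated_with_warning(self):
        df = _repeat_df(np.random.default_rng(7), sd_ia=0.1)
        df = pd.concat([df, df.iloc[[0]].assign(technical_rep="t9")])
        with pytest.warns(UserWarning, match="unbalanced"):
            res = repeatability(df)
        assert res.n_tech == 3


def _ip_df(rng, d=4, a=2, n=3, mean=10.0, sd_sp=0.1, sd_da=0.0, sd_a=0.0):
    day_eff = rng.normal(0, sd_da, d) if sd_da else np.zeros(d)
    an_eff = rng.normal(0, sd_a, a) if sd_a else np.zeros(a)
    rows = []
    for di in range(d):
        e_d = day_eff[di]
        for ai in range(a):
            e_a = an_eff[ai]
            for k in range(n):
                rows.append(
                    dict(day=f"d{di}", analyst=f"a{ai}", biological_rep=f"b{k}",
                         value=mean + e_d + e_a + rng.normal(0, sd_sp))
                )
    return pd.DataFrame(rows)


class TestIntermediatePrecision:
    def test_single_analyst_reports_nt(self):
        df = _ip_df(np.random.default_rng(8), a=1)
        res = intermediate_precision(df)
        assert res.weight("A") is None
        assert res.weight("SP") + res.weight("DA") == pytest.approx(100.0)

    def test_day_effects_dominate_as_noise_vanishes(self):
        rng = np.random.default_rng(9)
        weights = []
        for _ in range(50):
            df = _ip_df(rng, sd_sp=0.005, sd_da=0.3)
            weights.append(intermediate_precision(df).weight("DA"))
        assert np.mean(weights) > 95.0

    def test_symmetric_components_near_equal_weights(self):
        """Equal generating SDs: mean variance components split ~evenly.

        Weights are formed from across-seed mean variances; per-seed weights
        are skewed by the 1-df analyst mean square and zero-truncation.
        """
        rng = np.random.default_rng(10)
        v = {"SP": [], "DA": [], "A": []}
        for _ in range(400):
            df = _ip_df(rng, d=4, a=2, n=3, sd_sp=0.1, sd_da=0.1, sd_a=0.1)
            res = intermediate_precision(df)
            for f in v:
                v[f].append(res.components[f][0])
        means = {f: np.mean(vals) for f, vals in v.items()}
        total = sum(means.values())
        for f in means:
            assert 100 * means[f] / total == pytest.approx(100 / 3, abs=8.0)

    def test_needs_two_days(self):
        df = _ip_df(np.random.default_rng(11), d=1)
        with pytest.raises(ValueError, match="2 days"):
            intermediate_precision(df)


class TestStability:
    def test_identical_means_stable(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            [dict(day=f"d{d}", value=10 + rng.normal(0, 0.1)) for d in range(3) for _ in range(3)]
        )
        stable, pvals = stability_test(df)
        assert stable and len(pvals) == 2

    def test_large_shift_unstable(self):
        rng = np.random.default_rng(13)
        rows = [dict(day="d0", value=10 + rng.normal(0, 0.1)) for _ in range(3)]
        rows += [dict(day="d1", value=10 + rng.normal(0, 0.1)) for _ in range(3)]
        rows += [dict(day="d2", value=10.8 + rng.normal(0, 0.1)) for _ in range(3)]
        stable, pvals = stability_test(pd.DataFrame(rows))
        assert not stable and pvals["d2"] < 0.05

    def test_single_replicate_rejected(self):
        df = pd.DataFrame([dict(day="d0", value=1.0), dict(day="d1", value=1.0)])
        with pytest.raises(ValueError, match="2 replicates"):
            stability_test(df)


class TestRecovery:
    def _qr(self, value, quantifiable=True):
        return QuantResult(
            allergen_name="Peanut", x0_peptide=1.0, x0_tafp=value,
            detected=True, quantifiable=quantifiable,
        )

    def test_equal_contents_100_percent(self):
        res = recovery(self._qr(40.0), self._qr(40.0), "p-TAN")
        assert res.recovery_percent == pytest.approx(100.0)

    def test_53_percent_attenuation(self):
        res = recovery(self._qr(0.53 * 40.0), self._qr(40.0), "p-TAN")
        assert res.recovery_percent == pytest.approx(53.0)

    def test_sa_below_loq_rejected(self):
        with pytest.raises(ValueError, match="quantifiable"):
            recovery(self._qr(20.0), self._qr(40.0, quantifiable=False))
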