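"""Tests for expression grouping, paired t-tests and method concordance."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rrbskit import (
    Gene,
    group_by_expression,
    method_concordance,
    paired_t_test,
    stratified_tss_profiles,
    tss_meta_profile,
    window_difference_test,
)


class TestGroupByExpression:
    def test_threshold_and_median_split(self):
        groups = group_by_expression({"g1": 0, "g2": 9, "g3": 10, "g4": 1000})
        assert groups == {"g1": "repressed", "g2": "repressed",
                          "g3": "low", "g4": "high"}

    def test_all_repressed(self):
        groups = group_by_expression({"a": 0, "b": 5})
        assert set(groups.values()) == {"repressed"}

    def test_sixty_twenty_twenty(self):
        counts = {f"g{i:03d}": (5 if i < 60 else 10 + i) for i in range(100)}
        groups = group_by_expression(counts)
        from collections import Counter
        c = Counter(groups.values())
        assert c["repressed"] == 60 and c["low"] == 20 and c["high"] == 20

    def test_odd_remainder_extra_goes_to_low(self):
        groups = group_by_expression({"a": 10, "b": 20, "c": 30})
        assert [groups[k] for k in "abc"] == ["low", "low", "high"]

    def test_order_invariance(self):
        counts = {f"g{i}": i * 7 % 50 for i in range(30)}
        shuffled = dict(sorted(counts.items(), key=lambda kv: -kv[1]))
        assert group_by_expression(counts) == group_by_expression(shuffled)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            group_by_expression({})


class TestPairedTTest:
    def test_all_zero_degenerate(self):
        res = paired_t_test([0, 0, 0])
        assert res.degenerate and res.p == 1.0 and res.mean_diff == 0.0

    def test_worked_example(self):
        res = paired_t_test([1, 2, 3])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.t == pytest.approx(2 * math.sqrt(3))
        assert res.df == 2
        # closed-form oracle: two-sided p from the t CDF
        p_oracle = 2 * (1 - stats.t.cdf(2 * math.sqrt(3), 2))
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.p == pytest.approx(0.0742, abs=2e-4)

    def test_constant_shift_degenerate_p_zero(self):
        res = paired_t_test([5, 5, 5])
        assert res.degenerate and res.p == 0.0

    def test_insufficient_pairs(self):
        with pytest.raises(ValueError, match="insufficient_pairs"):
            paired_t_test([1.0])

    def test_sed_definition(self):
        d = [1.0, 4.0, 7.0, 10.0]
        res = paired_t_test(d)
        assert res.sed == pytest.approx(np.std(d, ddof=1) / 2)

    def test_matches_independent_oracle(self, rng):
        """1,000 random inputs against scipy's one-sample t-test."""
        for _ in range(1_000):
            n = int(rng.integers(2, 12))
            d = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 5), size=n)
            res = paired_t_test(d)
            t_ref, p_ref = stats.ttest_1samp(d, 0.0)
            assert abs(res.p - p_ref) < 1e-9
            assert res.t == pytest.approx(t_ref)


class TestMethodConcordance:
    def _frame(self, values):
        return pd.DataFrame(values,
                            columns=["an1", "an2", "an3"])

    def test_identity_all_indistinguishable(self, rng):
        a = self._frame(rng.uniform(0, 100, size=(20, 3)))
        res = method_concordance(a, a.copy())
        assert res.summary == "20/20"

    def test_constant_shift_flagged(self, rng):
        a = self._frame(rng.uniform(0, 100, size=(5, 3)))
        b = a.copy()
        b.iloc[2] += 50.0  # sd of d = 0, mean != 0 -> degenerate p = 0
        res = method_concordance(a, b)
        assert res.n_indistinguishable == 4
        row = res.per_site.set_index("site").loc[2]
        assert not row["indistinguishable"] and row["degenerate"]

    def test_site_mismatch_excluded(self, rng):
        a = self._frame(rng.uniform(0, 100, size=(6, 3)))
        b = a.copy().drop(index=[5])
        res = method_concordance(a, b)
        assert res.n_sites == 5 and res.excluded == [5]

    def test_needs_two_animals(self):
        a = pd.DataFrame({"an1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            method_concordance(a, a)

    def test_simulated_134_sites(self, rng):
        """3 animals, technical noise sd 2, two sites truly shifted."""
        base = rng.uniform(5, 95, size=134)
        a = self._frame(np.tile(base[:, None], 3) + rng.normal(0, 1, (134, 3)))
        b = a + rng.normal(0, 2, (134, 3))
        b.iloc[10] += 30.0
        b.iloc[50] += 30.0
        res = method_concordance(a, b)
        flagged = set(res.per_site[~res.per_site["indistinguishable"]]["site"])
        assert {10, 50} <= flagged
        # remaining sites are null; the t-test rejects ~5% of them
        assert 120 <= res.n_indistinguishable <= 132

    def test_bonferroni_option(self, rng):
        a = self._frame(rng.uniform(0, 100, size=(30, 3)))
        b = a + rng.normal(0, 2, (30, 3))
        plain = method_concordance(a, b)
        strict = method_concordance(a, b, bonferroni=True)
        assert strict.n_indistinguishable >= plain.n_indistinguishable


class TestTypeICalibration:
    def test_null_rejection_rate_near_nominal(self, rng):
        """500 null windows across 3 animals reject at ~5%."""
        n_reject = 0
        for _ in range(500):
            d = rng.normal(0.0, 1.0, size=3)
            n_reject += paired_t_test(d).p < 0.05
        assert 0.025 <= n_reject / 500 <= 0.08


class TestStratifiedProfiles:
    def test_single_stratum_equals_unstratified(self, acc_scenario, acc_calls):
        table, _ = acc_calls
        from rrbskit import filter_by_coverage
        calls = filter_by_coverage(table, 10)
        genes = acc_scenario["genes"]
        lengths = acc_scenario["lengths"]
        groups = {g.gene_id: "high" for g in genes}
        cpg = {g.gene_id: "high" for g in genes}
        strat = stratified_tss_profiles({"an1": calls}, genes, groups, cpg,
                                        lengths)
        plain = tss_meta_profile(calls, genes, lengths)
        prof = strat[("high", "high", "an1")]
        assert np.allclose(prof.mean, plain.mean, equal_nan=True)
        # the other strata are empty and flagged
        assert strat[("repressed", "high", "an1")] is None

    def test_two_route_sign_consistency(self, acc_scenario, strat_scenario):
        """Per-animal differences and pooled differences agree in sign."""
        from rrbskit import CpGCallTable, group_by_expression
        genes = acc_scenario["genes"]
        lengths = acc_scenario["lengths"]
        groups = group_by_expression(strat_scenario["expression"])
        high = [g for g in genes if groups[g.gene_id] == "high"]
        rep = [g for g in genes if groups[g.gene_id] == "repressed"]
        per_animal_diffs = []
        pooled = CpGCallTable()
        for calls in strat_scenario["calls_by_animal"].values():
            ph = tss_meta_profile(calls, high, lengths)
            pr = tss_meta_profile(calls, rep, lengths)
            per_animal_diffs.append(ph.mean - pr.mean)
            for (contig, pos), (m, u) in calls.data.items():
                row = pooled.data.setdefault((contig, pos), [0, 0])
                row[0] += m
                row[1] += u
        ph = tss_meta_profile(pooled, high, lengths)
        pr = tss_meta_profile(pooled, rep, lengths)
        pooled_diff = ph.mean - pr.mean
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cols
            mean_diff = np.nanmean(np.vstack(per_animal_diffs), axis=0)
        # compare signs where the effect is clearly nonzero in both routes
        mask = (~np.isnan(pooled_diff) & ~np.isnan(mean_diff)
                & (np.abs(pooled_diff) > 5) & (np.abs(mean_diff) > 5))
        assert mask.sum() >= 10
        assert (np.sign(pooled_diff[mask]) == np.sign(mean_diff[mask])).all()

    def test_window_difference_test_frame(self, acc_scenario, strat_scenario):
        from rrbskit import group_by_expression
        genes = acc_scenario["genes"]
        lengths = acc_scenario["lengths"]
        groups = group_by_expression(strat_scenario["expression"])
        high = [g for g in genes if groups[g.gene_id] == "high"]
        rep = [g for g in genes if groups[g.gene_id] == "repressed"]
        animals = sorted(strat_scenario["calls_by_animal"])
        pa = [tss_meta_profile(strat_scenario["calls_by_animal"][a], high,
                               lengths) for a in animals]
        pb = [tss_meta_profile(strat_scenario["calls_by_animal"][a], rep,
                               lengths) for a in animals]
        df = window_difference_test(pa, pb)
        assert list(df.columns) == ["offset", "mean_diff", "sed", "t", "p"]
        assert len(df) == 221
        # spot-check one defined window against a direct computation
        defined = df.dropna()
        assert len(defined) > 0
        w = int(defined.index[0])
        d = [pa[i].mean[w] - pb[i].mean[w] for i in range(3)]
        res = paired_t_test(d)
        assert df.loc[w, "p"] == pytest.approx(res.p)
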