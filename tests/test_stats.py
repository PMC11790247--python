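"""Grubbs gate, normality-gated comparisons, longitudinal analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aismorph.stats_report import (GroupData, compare_groups, dunn_posthoc,
                                   grubbs_critical_value, grubbs_outliers,
                                   longitudinal_analysis, plasticity_summary,
                                   two_group_ttest)


class TestGrubbs:
    def test_no_outlier_in_tight_sample(self):
        retained, removed = grubbs_outliers([8, 9, 10, 11])
        assert removed.size == 0
        assert retained.tolist() == [8, 9, 10, 11]

    def test_gross_outlier_removed(self):
        # G = (50 - 19.25) / 20.53 = 1.498 > Gcrit(4, 0.05) = 1.481
        values = [8, 9, 10, 50]
        g = (50 - np.mean(values)) / np.std(values, ddof=1)
        assert g > grubbs_critical_value(4)
        retained, removed = grubbs_outliers(values)
        assert removed.tolist() == [50]
        assert sorted(retained.tolist()) == [8, 9, 10]

    def test_undefined_below_three(self):
        with pytest.raises(ValueError):
            grubbs_outliers([1.0, 2.0])

    def test_critical_value_calibrated_by_simulation(self):
        # brute force: under the null, the Grubbs statistic exceeds the
        # two-sided critical value with probability ~alpha
        r = np.random.default_rng(1)
        n, n_sim = 8, 20000
        x = r.standard_normal((n_sim, n))
        g = np.max(np.abs(x - x.mean(axis=1, keepdims=True)), axis=1) \
            / x.std(axis=1, ddof=1)
        rate = np.mean(g > grubbs_critical_value(n, 0.05))
        assert rate == pytest.approx(0.05, abs=0.012)

    def test_removal_decreases_max_abs_z(self, rng):
        for _ in range(20):
            x = np.append(rng.normal(0, 1, 10), rng.uniform(5, 20))
            retained, removed = grubbs_outliers(x)
            if removed.size == 0:
                continue
            def max_z(v):
                return np.max(np.abs(v - v.mean())) / v.std(ddof=1)
            assert max_z(retained) < max_z(x)


class TestCompareGroups:
    def test_duplicated_group_null(self, rng):
        a = rng.normal(10, 2, 30)
        res = compare_groups(GroupData(np.concatenate([a, a]),
                                       np.repeat(["x", "y"], 30)))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_t_statistic_matches_hand_formula_n3(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 9.0])
        res = two_group_ttest(a, b)
        sp = np.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2) * (2 / 3))
        t_hand = (a.mean() - b.mean()) / sp
        assert res.statistic == pytest.approx(t_hand)
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(abs(t_hand), 4))

    def test_mann_whitney_matches_rank_enumeration(self):
        # exact two-sided p by enumerating all label assignments (n=3+3)
        a, b = [1.2, 3.4, 5.1], [2.2, 8.8, 9.9]
        res = compare_groups(
            GroupData(np.array(a + b), np.repeat(["a", "b"], 3)),
            normality="nonnormal")
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:3].sum() - 3 * 4 / 2
        us = []
        for combo in itertools.combinations(range(6), 3):
            u = ranks[list(combo)].sum() - 3 * 4 / 2
            us.append(u)
        us = np.array(us)
        mean_u = 3 * 3 / 2
        p_exact = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-9)
        assert res.test_name == "mann-whitney"
        assert res.p_value == pytest.approx(p_exact)

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        n_sim = 1000
        labels = np.repeat(["a", "b"], 50)
        for _ in range(n_sim):
            values = rng.standard_normal(100)
            if compare_groups(GroupData(values, labels)).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_anova_tukey_flags_only_shifted_pair(self, rng):
        g = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                            rng.normal(3, 1, 20)])
        res = compare_groups(GroupData(g, np.repeat(["a", "b", "c"], 20)),
                             normality="normal")
        assert res.test_name == "one-way ANOVA + Tukey"
        assert res.p_value < 0.001
        ph = res.posthoc.set_index(["group_1", "group_2"])["p_adj"]
        assert ph[("a", "b")] > 0.05
        assert ph[("a", "c")] < 0.001
        assert ph[("b", "c")] < 0.001

    def test_kruskal_dunn_branch(self, rng):
        g = [rng.exponential(1, 15), rng.exponential(1, 15),
             rng.exponential(5, 15)]
        res = compare_groups(
            GroupData(np.concatenate(g), np.repeat(["a", "b", "c"], 15)),
            normality="nonnormal")
        assert res.test_name == "kruskal-wallis + Dunn"
        ph = res.posthoc.set_index(["group_1", "group_2"])["p_adj"]
        assert ph[("a", "c")] < 0.05
        assert (res.posthoc["p_adj"] <= 1.0).all()

    def test_label_permutation_symmetry(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        d1 = GroupData(np.concatenate([a, b]), np.repeat(["a", "b"], 12))
        d2 = GroupData(np.concatenate([b, a]), np.repeat(["a", "b"], 12))
        assert compare_groups(d1).p_value == pytest.approx(
            compare_groups(d2).p_value)

    def test_paired_requires_complete_pairs(self):
        data = GroupData(np.arange(5.0), np.array(["a", "a", "a", "b", "b"]),
                        pairing_ids=np.array([0, 1, 2, 0, 1]))
        with pytest.raises(ValueError):
            compare_groups(data)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(GroupData(np.array([1.0, 2.0, 3.0]),
                                     np.array(["a", "a", "b"])))

    def test_dunn_bonferroni_capped(self, rng):
        groups = {g: rng.normal(0, 1, 10) for g in "abcd"}
        tab = dunn_posthoc(groups)
        assert len(tab) == 6
        assert (tab["p_adj"] <= 1.0).all()


class TestLongitudinal:
    def test_identical_sessions_degenerate(self):
        comp, reg = longitudinal_analysis([10.0, 12.0, 14.0],
                                          [10.0, 12.0, 14.0])
        assert "degenerate-differences" in comp.flags
        assert np.isnan(comp.p_value)
        assert reg.r_squared == pytest.approx(1.0)

    def test_paired_type_one_error(self, rng):
        n_sim, rejections = 1000, 0
        for _ in range(n_sim):
            w1 = rng.normal(17.3, 3.9, 30)
            w2 = w1 + rng.normal(0.0, 1.8, 30)
            comp, _ = longitudinal_analysis(w1, w2)
            if comp.p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_uncorrelated_r_squared_near_zero(self, rng):
        r2 = [longitudinal_analysis(rng.normal(17, 4, 30),
                                    rng.normal(17, 4, 30))[1].r_squared
              for _ in range(300)]
        assert np.mean(r2) < 0.05

    def test_pair_ordering_respected(self, rng):
        w1 = rng.normal(17, 4, 10)
        w2 = w1 + 1.0
        order = rng.permutation(10)
        comp, reg = longitudinal_analysis(w1[order], w2[order],
                                          pairs=order[np.argsort(order)])
        assert reg.r_squared == pytest.approx(1.0)


class TestPlasticitySummary:
    @staticmethod
    def frame(cond_means, n_otc=6, n_ais=50, sd=3.0, seed=0):
        r = np.random.default_rng(seed)
        rows = []
        for cond, mean in cond_means.items():
            for otc in range(n_otc):
                for v in r.normal(mean, sd, n_ais):
                    rows.append({"condition": cond, "otc": otc,
                                 "length_um": v})
        return pd.DataFrame(rows)

    def test_identical_conditions_null(self):
        df = self.frame({"a": 27.9, "b": 27.9})
        summary, comp = plasticity_summary(df)
        means = dict(zip(summary["condition"], summary["mean"]))
        assert means["a"] - means["b"] == pytest.approx(0.0, abs=0.5)
        assert comp.p_value > 0.05
        assert set(summary.columns) >= {"mean", "median", "sd", "n"}

    def test_condition_difference_recovered(self):
        df = self.frame({"ctrl": 27.9, "mgso4": 32.1})
        summary, comp = plasticity_summary(df)
        means = dict(zip(summary["condition"], summary["mean"]))
        # 2 SEM of each condition mean at n = 300 AIS
        sem = 3.0 / np.sqrt(300)
        assert means["mgso4"] - means["ctrl"] == pytest.approx(
            4.2, abs=2 * np.sqrt(2) * 2 * sem)
        assert comp.p_value < 0.01
        assert summary.loc[summary.condition == "ctrl", "n"].iloc[0] == 6

    def test_single_otc_condition_refused_but_summarized(self):
        df = pd.concat([self.frame({"a": 27.9, "b": 32.1}),
                        self.frame({"c": 30.0}, n_otc=1)],
                       ignore_index=True)
        summary, comp = plasticity_summary(df)
        assert set(summary["condition"]) == {"a", "b", "c"}
        assert any(f.startswith("comparison-refused") for f in comp.flags)
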