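import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import (bh_adjust_bruteforce, chi2_bruteforce,
                     kruskal_h_bruteforce, mann_whitney_p_exhaustive)
from rseeg.stats import (anova_from_summary, channelwise_group_analysis,
                         chi_squared_contingency, fdr_adjust, kruskal_wallis,
                         mann_whitney_u, pearson_bootstrap, posthoc_dunn,
                         posthoc_tukey, t_test_from_summary)


class TestKruskalWallis:
    def test_worked_example_matches_rank_definition(self):
        groups = ([1, 2], [3, 4], [5, 6])
        h, df, p = kruskal_wallis(*groups)
        assert h == pytest.approx(4.571, abs=5e-4)
        assert h == pytest.approx(kruskal_h_bruteforce(groups), rel=1e-12)
        assert df == 2

    def test_identical_groups_degenerate(self):
        h, df, p = kruskal_wallis([2.0, 2.0], [2.0, 2.0], [2.0, 2.0])
        assert h == 0.0 and p == 1.0 and df == 2

    def test_matches_bruteforce_with_ties(self, rng):
        groups = [rng.integers(0, 5, size=8).astype(float) for _ in range(3)]
        h, _, _ = kruskal_wallis(*groups)
        assert h == pytest.approx(kruskal_h_bruteforce(groups), rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0])
        with pytest.raises(ValueError):
            kruskal_wallis([1.0], [2.0])


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04], atol=1e-12)

    def test_all_equal_stay_equal(self):
        adj = fdr_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(adj, adj[0])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_properties_vs_bruteforce(self, ps):
        adj = fdr_adjust(ps)
        np.testing.assert_allclose(adj, bh_adjust_bruteforce(ps), atol=1e-12)
        assert (adj >= np.asarray(ps) - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-15).all()  # monotone in p rank


class TestTukey:
    def test_identical_groups_p_near_one(self, rng):
        x = rng.normal(size=20)
        out = posthoc_tukey({"a": x, "b": x.copy()})
        assert out["p"].iloc[0] > 0.99

    def test_separated_groups_tiny_p(self, rng):
        out = posthoc_tukey({"a": rng.normal(0, 0.1, 20),
                             "b": rng.normal(10, 0.1, 20),
                             "c": rng.normal(20, 0.1, 20)})
        assert (out["p"] < 0.001).all()
        assert list(out["direction"]) == ["a<b", "a<c", "b<c"]

    def test_matches_studentized_range_definition(self, rng):
        groups = {k: rng.normal(size=n)
                  for k, n in (("a", 8), ("b", 10), ("c", 7))}
        out = posthoc_tukey(groups)
        # oracle: Tukey-Kramer q statistic + studentized range distribution
        ns = {k: len(v) for k, v in groups.items()}
        df = sum(ns.values()) - 3
        msw = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
        for _, row in out.iterrows():
            na, nb = ns[row.group_a], ns[row.group_b]
            q = abs(row.mean_diff) / np.sqrt(msw / 2 * (1 / na + 1 / nb))
            p_oracle = sps.studentized_range.sf(q, 3, df)
            assert row.p == pytest.approx(p_oracle, abs=1e-6)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            posthoc_tukey({"a": np.ones(5), "b": np.full(5, 2.0)})

    def test_dunn_directions_match_tukey_on_separated_data(self, rng):
        groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(5, 1, 15)}
        t = posthoc_tukey(groups)
        d = posthoc_dunn(groups)
        assert list(t["direction"]) == list(d["direction"])
        assert d["p"].iloc[0] < 0.01


class TestSummaryTests:
    def test_years_smoking_t(self):
        t, df, p = t_test_from_summary(37.80, 7.54, 20, 10.21, 6.43, 28)
        assert t == pytest.approx(13.63, abs=0.02)
        assert df == 46

    def test_ftnd_t(self):
        t, df, p = t_test_from_summary(5.58, 2.09, 19, 3.15, 3.17, 20)
        assert t == pytest.approx(2.81, abs=0.02)
        assert df == 37

    def test_equal_means_zero(self):
        t, df, p = t_test_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_raw_data_pooled_t(self, rng):
        x, y = rng.normal(0, 1, 14), rng.normal(0.5, 2, 9)
        t_raw, p_raw = sps.ttest_ind(x, y, equal_var=True)
        t, df, p = t_test_from_summary(x.mean(), x.std(ddof=1), len(x),
                                       y.mean(), y.std(ddof=1), len(y))
        assert t == pytest.approx(t_raw, rel=1e-12)
        assert p == pytest.approx(p_raw, rel=1e-12)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            t_test_from_summary(1, 0, 5, 2, 0, 5)
        with pytest.raises(ValueError):
            t_test_from_summary(1, 1, 1, 2, 1, 5)

    def test_age_anova(self):
        f, df1, df2, p = anova_from_summary([53.09, 54.64, 56.30],
                                            [4.96, 6.48, 7.12], [33, 28, 20])
        assert f == pytest.approx(1.76, abs=0.02)
        assert (df1, df2) == (2, 78)

    def test_identical_means_zero_f(self):
        f, *_ = anova_from_summary([3.0, 3.0], [1.0, 1.5], [10, 12])
        assert f == 0.0

    def test_two_group_f_equals_t_squared(self, rng):
        x, y = rng.normal(size=12), rng.normal(1, 1.5, size=17)
        t, _, pt = t_test_from_summary(x.mean(), x.std(ddof=1), 12,
                                       y.mean(), y.std(ddof=1), 17)
        f, _, _, pf = anova_from_summary([x.mean(), y.mean()],
                                         [x.std(ddof=1), y.std(ddof=1)], [12, 17])
        assert f == pytest.approx(t**2, rel=1e-10)
        assert pf == pytest.approx(pt, rel=1e-10)

    def test_anova_matches_raw_f(self, rng):
        samples = [rng.normal(m, 1, 10) for m in (0, 0.4, 1.0)]
        f_raw, p_raw = sps.f_oneway(*samples)
        f, _, _, p = anova_from_summary([s.mean() for s in samples],
                                        [s.std(ddof=1) for s in samples],
                                        [10, 10, 10])
        assert f == pytest.approx(f_raw, rel=1e-12)


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_midpoint(self):
        u, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == 4.5  # n1*n2/2

    def test_exact_p_matches_exhaustive_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(0.8, 1, size=5)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mann_whitney_p_exhaustive(x, y), abs=1e-10)

    def test_tied_data_uses_corrected_normal(self):
        x = [1, 1, 2, 2, 3, 3, 4, 4]
        y = [2, 2, 3, 3, 4, 4, 5, 5]
        u, p = mann_whitney_u(x, y)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(res.pvalue)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestChiSquared:
    def test_independent_table_zero(self):
        table = np.array([[10, 20], [20, 40]])
        chi2, df, p = chi_squared_contingency(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df_for_5_levels_by_3_groups(self, rng):
        table = rng.integers(1, 20, size=(5, 3))
        _, df, _ = chi_squared_contingency(table)
        assert df == 8

    def test_matches_direct_formula(self, rng):
        table = rng.integers(1, 30, size=(3, 4))
        chi2, _, _ = chi_squared_contingency(table)
        assert chi2 == pytest.approx(chi2_bruteforce(table), rel=1e-12)

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_contingency([[0, 0], [1, 2]])


class TestPearsonBootstrap:
    def test_perfect_correlation_degenerate_ci(self, rng):
        x = rng.normal(size=30)
        res = pearson_bootstrap(x, x, n_boot=1000, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)
        assert res.p_boot == 2 / 1000  # floor

    def test_bit_exact_reproducibility(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        a = pearson_bootstrap(x, y, n_boot=2000, seed=42)
        b = pearson_bootstrap(x, y, n_boot=2000, seed=42)
        assert (a.r, a.p_boot, a.ci_low, a.ci_high) == \
            (b.r, b.p_boot, b.ci_low, b.ci_high)

    def test_pairwise_complete_deletion(self, rng):
        x = rng.normal(size=50)
        y = 0.9 * x + 0.3 * rng.normal(size=50)
        x[[3, 7]] = np.nan
        y[10] = np.nan
        res = pearson_bootstrap(x, y, n_boot=1000, seed=0)
        assert res.n == 47
        ok = np.isfinite(x) & np.isfinite(y)
        assert res.r == pytest.approx(np.corrcoef(x[ok], y[ok])[0, 1])

    def test_ci_brackets_point_estimate(self, rng):
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        res = pearson_bootstrap(x, y, n_boot=4000, seed=3)
        assert res.ci_low < res.r < res.ci_high

    def test_validation_errors(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="n_boot"):
            pearson_bootstrap(x, x, n_boot=10, seed=0)
        with pytest.raises(ValueError, match="zero variance"):
            pearson_bootstrap(np.ones(20), x, seed=0)
        with pytest.raises(ValueError, match="complete"):
            pearson_bootstrap([1.0, 2.0], [1.0, 2.0], seed=0)


class TestChannelwiseAnalysis:
    @staticmethod
    def _power_table(rng, effect_channel=None, n=12):
        rows = []
        for group, shift in (("never", 0.0), ("past", 0.0), ("smoker", 1.0)):
            for i in range(n):
                for ch in ("C3", "C4", "Oz"):
                    val = rng.normal()
                    if effect_channel == ch:
                        val += shift * 4.0
                    rows.append((f"{group}{i}", group, "EC", ch, "theta", val))
        return pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                           "channel", "band", "relative_power"])

    def test_planted_effect_flagged_with_direction(self, rng):
        table = self._power_table(rng, effect_channel="C3")
        rep = channelwise_group_analysis(table, "relative_power", "theta", "EC")
        assert rep.significant_units == ["C3"]
        ph = rep.posthoc
        row = ph[(ph.group_a == "never") & (ph.group_b == "smoker")].iloc[0]
        assert row.direction == "never<smoker" and row.p < 0.05

    def test_null_table_unlikely_significant(self, rng):
        rep = channelwise_group_analysis(self._power_table(rng),
                                         "relative_power", "theta", "EC")
        assert len(rep.significant_units) == 0
        assert (rep.table["p_fdr"] >= rep.table["p_raw"] - 1e-15).all()

    def test_validation(self, rng):
        table = self._power_table(rng, n=2)
        with pytest.raises(ValueError, match="3 subjects"):
            channelwise_group_analysis(table, "relative_power", "theta", "EC")
        with pytest.raises(ValueError, match="unknown feature"):
            channelwise_group_analysis(table, "phase", "theta", "EC")
        with pytest.raises(ValueError, match="no rows"):
            channelwise_group_analysis(table, "relative_power", "sigma", "EC")
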