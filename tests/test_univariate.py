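"""ANOVA variants, assumption checks, the alpha-adjustment gate and Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from opilio.univariate import (
    anderson_darling,
    heteroscedastic_gate,
    levene_test,
    nested_anova,
    one_way_anova,
    tukey_hsd,
    two_way_anova,
)


class TestOneWay:
    def test_hand_computed_example(self):
        res = one_way_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        term = res.term("group")
        assert term.F == pytest.approx(13.5, rel=1e-12)
        assert term.p == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-12)
        assert term.p == pytest.approx(0.0213, abs=2e-4)

    def test_order_invariance(self, rng):
        y = rng.normal(size=15)
        g = np.repeat(["a", "b", "c"], 5)
        perm = rng.permutation(15)
        r1 = one_way_anova(y, g).table
        r2 = one_way_anova(y[perm], g[perm]).table
        pd.testing.assert_frame_equal(r1, r2)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_ss_additivity(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(list("abc"), 10)
        res = one_way_anova(y, g)
        total = ((y - y.mean()) ** 2).sum()
        assert res.table.SS.sum() == pytest.approx(total, abs=1e-9)


class TestTwoWay:
    def _balanced(self, rng, effect_a=1.0):
        a = np.repeat(["x", "y", "z"], 10)
        b = np.tile(np.repeat(["p", "q"], 5), 3)
        y = rng.normal(size=30, scale=0.5) + (a == "y") * effect_a
        return y, a, b

    def test_matches_statsmodels_sequential(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y, a, b = self._balanced(rng)
        # unbalance it: drop a few observations
        keep = np.ones(30, bool)
        keep[[0, 7, 13]] = False
        res = two_way_anova(y[keep], a[keep], b[keep])
        df = pd.DataFrame({"y": y[keep], "a": a[keep], "b": b[keep]})
        ref = sm.stats.anova_lm(smf.ols("y ~ C(a) + C(b) + C(a):C(b)", df).fit(), typ=1)
        for term, ref_row in zip(("A", "B", "A:B"), ("C(a)", "C(b)", "C(a):C(b)")):
            assert res.term(term).SS == pytest.approx(ref.loc[ref_row, "sum_sq"], rel=1e-8)
            assert res.term(term).F == pytest.approx(ref.loc[ref_row, "F"], rel=1e-8)
        assert not res.balanced

    def test_constant_second_factor_collapses_to_one_way(self, rng):
        y, a, _ = self._balanced(rng)
        res2 = two_way_anova(y, a, np.repeat("only", 30))
        res1 = one_way_anova(y, a)
        assert res2.term("A").F == pytest.approx(res1.term("group").F, rel=1e-10)
        assert res2.residual_df == res1.residual_df

    def test_factor_order_invariance_on_balanced_data(self, rng):
        y, a, b = self._balanced(rng)
        r1 = two_way_anova(y, a, b)
        r2 = two_way_anova(y, b, a, names=("B", "A"))
        for term in ("A", "B"):
            assert r1.term(term).SS == pytest.approx(r2.term(term).SS, rel=1e-9)

    def test_empty_cell_with_interaction_rejected(self):
        a = ["x", "x", "y", "y"]
        b = ["p", "p", "q", "q"]  # cells (x,q) and (y,p) empty
        with pytest.raises(ValueError, match="empty"):
            two_way_anova([1.0, 2.0, 3.0, 4.0], a, b)


class TestNested:
    def _nested_data(self, rng, unit_sd=1.0, treat_effect=0.0, units=4, reps=6):
        rows = []
        for ti, t in enumerate(("A", "B", "C")):
            for u in range(units):
                unit_eff = rng.normal(scale=unit_sd)
                for _ in range(reps):
                    rows.append({"t": t, "u": f"{t}{u}",
                                 "y": rng.normal(scale=0.5) + unit_eff + ti * treat_effect})
        return pd.DataFrame(rows)

    def test_treatment_tested_over_unit_mean_square(self, rng):
        df = self._nested_data(rng)
        res = nested_anova(df.y, df.t, df.u)
        ms_t = res.term("treatment").MS
        ms_u = res.term("unit").MS
        assert res.term("treatment").F == pytest.approx(ms_t / ms_u, rel=1e-12)
        assert res.term("treatment").p == pytest.approx(
            stats.f.sf(ms_t / ms_u, 2, 9), rel=1e-10)  # 12 units - 3 treatments

    def test_balanced_equivalence_with_anova_on_unit_means(self, rng):
        # for balanced designs, treatment F over the unit MS equals the
        # one-way F computed on per-unit means
        df = self._nested_data(rng, unit_sd=0.8, treat_effect=0.5)
        res = nested_anova(df.y, df.t, df.u)
        means = df.groupby(["t", "u"])["y"].mean().reset_index()
        ref = one_way_anova(means.y, means.t)
        assert res.term("treatment").F == pytest.approx(ref.term("group").F, rel=1e-9)

    def test_unit_spanning_treatments_rejected(self):
        with pytest.raises(ValueError, match="more than one treatment"):
            nested_anova([1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"],
                         ["u1", "u1", "u1", "u2"])

    def test_single_unit_per_treatment_rejected(self, rng):
        df = self._nested_data(rng, units=1)
        with pytest.raises(ValueError, match="degrees of freedom"):
            nested_anova(df.y, df.t, df.u)

    def test_crossed_factor_terms_present(self, rng):
        df = self._nested_data(rng)
        month = np.tile(["jan", "feb", "mar"], len(df) // 3)
        res = nested_anova(df.y, df.t, df.u, month)
        assert {"treatment", "unit", "crossed", "treatment:crossed", "Residual"} \
            <= set(res.table.term)


class TestAssumptionChecks:
    def test_levene_matches_scipy_and_detects_heterogeneity(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30, scale=4.0)
        y = np.concatenate([a, b])
        g = np.repeat(["a", "b"], 30)
        p = levene_test(y, g)
        assert p == stats.levene(a, b, center="mean").pvalue
        assert p < 0.01

    def test_levene_insufficient_n(self):
        with pytest.raises(ValueError):
            levene_test([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"])

    def test_anderson_darling_normal_vs_uniform(self, rng):
        assert anderson_darling(rng.normal(size=200)) > 0.05
        assert anderson_darling(rng.uniform(size=200)) < 0.01

    def test_anderson_darling_insufficient_n(self):
        with pytest.raises(ValueError):
            anderson_darling([1.0] * 7)


class TestGate:
    def test_homoscedastic_branch(self):
        d = heteroscedastic_gate(0.03, 0.5)
        assert d.significant and d.alpha_used == 0.05 and not d.heteroscedastic

    def test_heteroscedastic_not_significant(self):
        d = heteroscedastic_gate(0.03, 0.01)
        assert not d.significant and d.alpha_used == 0.01

    def test_heteroscedastic_extreme_evidence_still_significant(self):
        d = heteroscedastic_gate(1e-16, 1e-15)
        assert d.significant and d.heteroscedastic

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            heteroscedastic_gate(1.2, 0.5)


class TestTukey:
    def test_two_groups_equal_pooled_t(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8) + 0.8
        res = tukey_hsd(np.concatenate([a, b]), ["a"] * 8 + ["b"] * 8)
        t_p = stats.ttest_ind(a, b).pvalue
        assert res.pairwise.p_adj.iloc[0] == pytest.approx(t_p, rel=1e-7)

    def test_identical_groups_share_letter(self, rng):
        y = np.tile(rng.normal(size=6), 3)
        g = np.repeat(["a", "b", "c"], 6)
        res = tukey_hsd(y, g)
        assert (res.pairwise.p_adj > 0.99).all()
        assert len(set(res.letters.values())) == 1

    def test_shifted_group_gets_unique_letter(self, rng):
        y = np.concatenate([rng.normal(size=6), rng.normal(size=6),
                            rng.normal(size=6) + 10.0])
        g = np.repeat(["a", "b", "c"], 6)
        res = tukey_hsd(y, g)
        letters = res.letters
        assert letters["c"] not in (letters["a"], letters["b"])
        assert letters["a"] == letters["b"]

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "a"])
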