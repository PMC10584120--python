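"""Permutation multivariate statistics: agreement with independent
implementations, exact enumeration, and definitional bounds."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

import skbio.stats.distance as skdist

from opilio.multivariate import (
    DistanceMatrix,
    anosim,
    euclidean_distance_matrix,
    percent_difference,
    permanova,
    permdisp,
    simper,
    zscore_normalize,
)


class TestZscore:
    def test_three_point_column(self):
        out = zscore_normalize(pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
        assert np.allclose(out.v, [-1.0, 0.0, 1.0])  # n-1 denominator

    def test_idempotent(self, two_group_table):
        tbl, _ = two_group_table
        once = zscore_normalize(tbl)
        twice = zscore_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_centering(self, two_group_table):
        tbl, _ = two_group_table
        out = zscore_normalize(tbl)
        assert np.abs(out.mean()).max() < 1e-12
        assert np.allclose(out.std(ddof=1), 1.0)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="flat"):
            zscore_normalize(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


class TestDistanceMatrix:
    def test_euclidean_properties(self, two_group_table):
        tbl, _ = two_group_table
        dm = euclidean_distance_matrix(tbl)
        v = dm.values
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
        # spot-check one entry against direct computation
        direct = np.linalg.norm(tbl.iloc[0] - tbl.iloc[5])
        assert v[0, 5] == pytest.approx(direct, rel=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPermanova:
    def test_statistic_matches_skbio(self, two_group_table):
        tbl, groups = two_group_table
        dm = euclidean_distance_matrix(tbl)
        mine = permanova(dm, {"g": groups}, n_perm=99, seed=0)["g"].statistic
        ref = skdist.permanova(skdist.DistanceMatrix(dm.values), groups,
                               permutations=99)["test statistic"]
        assert mine == pytest.approx(ref, rel=1e-10)

    def test_single_variable_equals_classical_f(self, rng):
        y = rng.normal(size=14)
        y[7:] += 1.2
        g = np.array(["a"] * 7 + ["b"] * 7)
        dm = euclidean_distance_matrix(pd.DataFrame({"v": y}))
        pseudo_f = permanova(dm, {"g": g}, n_perm=9, seed=0)["g"].statistic
        assert pseudo_f == pytest.approx(f_oneway(y[:7], y[7:]).statistic, rel=1e-10)

    def test_exhaustive_p_equals_assignment_enumeration(self):
        y = np.array([0.1, 0.3, 0.2, 1.1, 1.4, 1.2])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        dm = euclidean_distance_matrix(pd.DataFrame({"v": y}))
        res = permanova(dm, {"g": g}, exhaustive=True)["g"]
        # independent brute force over the 20 distinct label assignments
        def fstat(labels):
            sa = y[np.array(labels) == "a"]
            sb = y[np.array(labels) == "b"]
            return f_oneway(sa, sb).statistic
        obs = fstat(g)
        hits = total = 0
        for pick in combinations(range(6), 3):
            labels = np.array(["b"] * 6)
            labels[list(pick)] = "a"
            hits += fstat(labels) >= obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(hits / total)
        assert res.exhaustive

    def test_two_factor_terms_on_crossed_design(self, rng):
        a = np.repeat(["x", "y"], 12)
        b = np.tile(np.repeat(["p", "q", "r"], 4), 2)
        y = rng.normal(size=24, scale=0.3) + (a == "y") * 2.0
        tbl = pd.DataFrame({"v1": y, "v2": rng.normal(size=24, scale=0.3)})
        res = permanova(euclidean_distance_matrix(tbl), {"A": a, "B": b},
                        n_perm=199, seed=1)
        assert set(res) == {"A", "B", "A:B"}
        assert res["A"].p_value <= 0.01
        assert res["B"].p_value > 0.05

    def test_identical_samples_rejected(self):
        dm = DistanceMatrix(np.zeros((6, 6)))
        with pytest.raises(ValueError, match="identical"):
            permanova(dm, {"g": ["a"] * 3 + ["b"] * 3}, n_perm=9)

    def test_singleton_level_rejected(self, two_group_table):
        tbl, _ = two_group_table
        dm = euclidean_distance_matrix(tbl)
        groups = np.array(["a"] + ["b"] * 19)
        with pytest.raises(ValueError, match="single sample"):
            permanova(dm, {"g": groups}, n_perm=9)

    def test_strata_restrict_permutations(self, rng):
        # with strata equal to the factor itself, no permutation can change
        # the statistic, so p must be 1
        tbl = pd.DataFrame(rng.normal(size=(12, 3)))
        g = np.array(["a"] * 6 + ["b"] * 6)
        dm = euclidean_distance_matrix(tbl)
        res = permanova(dm, {"g": g}, n_perm=99, seed=0, strata=g)["g"]
        assert res.p_value == 1.0


class TestPermdisp:
    def test_translated_copies_have_equal_dispersion(self):
        base = np.random.default_rng(0).normal(size=(8, 3))
        tbl = pd.DataFrame(np.vstack([base, base + 5.0]))
        groups = np.array(["a"] * 8 + ["b"] * 8)
        res = permdisp(euclidean_distance_matrix(tbl), groups, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.9

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3)) * 10.0
        tbl = pd.DataFrame(np.vstack([a, b]))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = permdisp(euclidean_distance_matrix(tbl), groups, n_perm=199, seed=0)
        assert res.statistic > 10
        assert res.p_value <= 0.02

    def test_statistic_matches_skbio_centroid(self, two_group_table):
        tbl, groups = two_group_table
        dm = euclidean_distance_matrix(tbl)
        mine = permdisp(dm, groups, n_perm=9, seed=0).statistic
        ref = skdist.permdisp(skdist.DistanceMatrix(dm.values), groups,
                              permutations=9, test="centroid")["test statistic"]
        assert mine == pytest.approx(ref, rel=1e-9)

    def test_singleton_group_rejected(self, two_group_table):
        tbl, _ = two_group_table
        dm = euclidean_distance_matrix(tbl)
        with pytest.raises(ValueError):
            permdisp(dm, np.array(["a"] + ["b"] * 19), n_perm=9)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        x = np.concatenate([np.zeros(4), np.full(4, 100.0)])
        dm = euclidean_distance_matrix(pd.DataFrame({"v": x + np.arange(8) * 0.01}))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res = anosim(dm, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_statistic_matches_skbio(self, two_group_table):
        tbl, groups = two_group_table
        dm = euclidean_distance_matrix(tbl)
        mine = anosim(dm, groups, n_perm=9, seed=0).statistic
        ref = skdist.anosim(skdist.DistanceMatrix(dm.values), groups,
                            permutations=9)["test statistic"]
        assert mine == pytest.approx(ref, rel=1e-10)

    def test_null_mean_r_near_zero(self, rng):
        rs = []
        g = np.array(["a"] * 5 + ["b"] * 5)
        for i in range(200):
            tbl = pd.DataFrame(rng.normal(size=(10, 3)))
            rs.append(anosim(euclidean_distance_matrix(tbl), g, n_perm=1, seed=i).statistic)
        assert abs(np.mean(rs)) < 0.03

    def test_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(3)
        tbl = pd.DataFrame(rng.normal(size=(6, 2)))
        g = np.array(["a", "a", "a", "b", "b", "b"])
        dm = euclidean_distance_matrix(tbl)
        res = anosim(dm, g, exhaustive=True)
        # independent enumeration over distinct assignments
        from scipy.stats import rankdata
        iu = np.triu_indices(6, k=1)
        ranks = rankdata(dm.values[iu])
        M = len(ranks)

        def r_stat(labels):
            within = labels[iu[0]] == labels[iu[1]]
            return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)
        obs = r_stat(g)
        hits = total = 0
        for pick in combinations(range(6), 3):
            labels = np.array(["b"] * 6)
            labels[list(pick)] = "a"
            hits += r_stat(labels) >= obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(hits / total)


class TestSimper:
    def test_single_axis_difference_contributes_everything(self):
        tbl = pd.DataFrame({"u": [1.0, 1.0, 3.0, 3.0], "v": [2.0, 2.0, 2.0, 2.0]})
        g = np.array(["a", "a", "b", "b"])
        out = simper(tbl, g)
        assert out.loc[out.variable == "u", "pct_contribution"].iloc[0] == 100.0

    def test_equal_offsets_split_evenly(self):
        tbl = pd.DataFrame({"u": [0.0, 0.0, 1.0, 1.0], "v": [5.0, 5.0, 6.0, 6.0]})
        out = simper(tbl, np.array(["a", "a", "b", "b"]))
        assert np.allclose(out.pct_contribution, 50.0)

    def test_contributions_sum_to_100(self, two_group_table):
        tbl, groups = two_group_table
        out = simper(tbl, groups)
        assert out.pct_contribution.sum() == pytest.approx(100.0, abs=1e-9)
        out_abs = simper(tbl, groups, mode="absolute")
        assert out_abs.pct_contribution.sum() == pytest.approx(100.0, abs=1e-9)

    def test_identical_groups_rejected(self):
        tbl = pd.DataFrame({"u": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            simper(tbl, np.array(["a", "a", "b", "b"]))


class TestPercentDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (2.89, 2.73, 5.5),    # carapace width, year-1 ambient vs pH 7.8
        (1.68, 1.83, -8.9),   # protopodite length, second treatment larger
        (3.0, 3.0, 0.0),
    ])
    def test_published_worked_values(self, a, b, expected):
        assert percent_difference(a, b) == pytest.approx(expected, abs=0.05)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)
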