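import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from ephygraze.community import (SimilarityMatrix, anosim, bray_curtis,
                                 clean_protist_table, lineage_at_rank,
                                 mann_whitney, rarefy,
                                 relative_abundance_profile,
                                 shared_otu_filter, upgma)
from ephygraze.core_io import OtuTable, SampleMeta, ValidationError


class TestCleanTable:
    def test_metazoa_removed(self, small_otu_table):
        out = clean_protist_table(small_otu_table, ["Metazoa"])
        assert out.otu_ids == ["o1", "o2"]

    def test_empty_exclusion_identity(self, small_otu_table):
        out = clean_protist_table(small_otu_table, [])
        assert out.otu_ids == small_otu_table.otu_ids

    def test_all_excluded(self, small_otu_table):
        out = clean_protist_table(small_otu_table, ["Eukaryota"])
        assert out.otu_ids == []

    def test_case_insensitive_whole_rank(self, small_otu_table):
        out = clean_protist_table(small_otu_table, ["metazoa"])
        assert "o3" not in out.otu_ids


class TestRarefy:
    def test_identity_at_full_depth(self, small_otu_table):
        depth = int(small_otu_table.counts.sum(axis=0).min())
        out = rarefy(small_otu_table, depth, repeats=3, seed=0)
        col = small_otu_table.counts.sum(axis=0).idxmin()
        pd.testing.assert_series_equal(out.counts[col],
                                       small_otu_table.counts[col])

    def test_hypergeometric_expectation(self):
        """Mean over many repeats approaches depth × count/total."""
        samples = [SampleMeta("s1", "T0", "control", 1)]
        t = OtuTable(pd.DataFrame({"s1": [50, 50]}, index=["A", "B"]),
                     pd.Series({"A": "x", "B": "y"}), samples)
        reps = 1000
        out = rarefy(t, 10, repeats=reps, seed=7)
        # Var of one draw = 10·0.5·0.5·(90/99) ≈ 2.27 → SE of mean ≈ 0.048
        assert out.counts.loc["A", "s1"] == pytest.approx(5, abs=2 * 0.1)

    def test_depth_zero(self, small_otu_table):
        out = rarefy(small_otu_table, 0, repeats=2, seed=0)
        assert (out.counts == 0).all().all()

    def test_depth_exceeds_total(self, small_otu_table):
        with pytest.raises(ValidationError, match="exceeds total"):
            rarefy(small_otu_table, 101, repeats=1, seed=0)

    def test_column_sums_near_depth(self, small_otu_table):
        repeats = 25
        out = rarefy(small_otu_table, 50, repeats=repeats, seed=3)
        sums = out.counts.sum(axis=0)
        assert ((sums - 50).abs() <= repeats).all()

    def test_deterministic_under_seed(self, small_otu_table):
        a = rarefy(small_otu_table, 50, repeats=10, seed=11)
        b = rarefy(small_otu_table, 50, repeats=10, seed=11)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestSharedOtuFilter:
    def _table(self, presence):
        samples = [SampleMeta(f"s{i}", "T0", "control", i) for i in (1, 2, 3)]
        counts = pd.DataFrame(presence, index=["o1", "o2", "o3"],
                              columns=["s1", "s2", "s3"])
        lin = pd.Series({o: "Euk;X" for o in counts.index})
        return OtuTable(counts, lin, samples)

    def test_missing_in_one_sample_removed(self):
        t = self._table([[5, 5, 0], [1, 1, 1], [2, 3, 4]])
        out = shared_otu_filter(t, {"g": ["s1", "s2", "s3"]})
        assert out.otu_ids == ["o2", "o3"]

    def test_brute_force_intersection(self):
        rng = np.random.default_rng(0)
        presence = rng.integers(0, 3, size=(3, 3))
        t = self._table(presence)
        groups = {"a": ["s1"], "b": ["s2"], "c": ["s3"]}
        out = shared_otu_filter(t, groups)
        expected = set(t.otu_ids)
        for members in groups.values():
            for s in members:
                expected &= set(t.counts.index[t.counts[s] > 0])
        assert set(out.otu_ids) == expected

    def test_empty_group_rejected(self):
        t = self._table([[1, 1, 1]] * 3)
        with pytest.raises(ValidationError, match="empty"):
            shared_otu_filter(t, {"a": ["s1", "s2", "s3"], "b": []})


class TestRelativeAbundanceProfile:
    def test_simple_percentages(self, small_otu_table):
        prof = relative_abundance_profile(small_otu_table, level=1,
                                          threshold=0.0)
        assert prof.ra["s1"].sum() == pytest.approx(100.0)
        assert prof.ra.loc["Alveolata", "s1"] == pytest.approx(50.0)
        assert prof.ra.loc["Stramenopiles", "s1"] == pytest.approx(30.0)

    def test_minor_category_lumped(self):
        samples = [SampleMeta("s1", "T0", "control", 1),
                   SampleMeta("s2", "T0", "control", 2)]
        counts = pd.DataFrame({"s1": [995, 5], "s2": [996, 4]},
                              index=["big", "tiny"])
        lin = pd.Series({"big": "Euk;Big", "tiny": "Euk;Tiny"})
        prof = relative_abundance_profile(OtuTable(counts, lin, samples), 1)
        assert "Tiny" not in prof.ra.index
        assert prof.ra.loc["Others", "s1"] == pytest.approx(0.5)
        assert prof.lumped == ["Tiny"]

    def test_unresolvable_rank(self):
        assert lineage_at_rank("Euk", 3) == "Unclassified"
        assert lineage_at_rank("Euk;Alv;Cil;Strom", "order") == "Strom"

    def test_zero_total_sample_rejected(self):
        samples = [SampleMeta("s1", "T0", "control", 1)]
        t = OtuTable(pd.DataFrame({"s1": [0]}, index=["o"]),
                     pd.Series({"o": "x"}), samples)
        with pytest.raises(ValidationError):
            relative_abundance_profile(t, 0)


class TestBrayCurtis:
    def test_hand_examples(self):
        df = pd.DataFrame({"x": [1.0, 3.0], "y": [3.0, 1.0]})
        assert bray_curtis(df).values[0, 1] == pytest.approx(50.0)
        ident = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        assert bray_curtis(ident).values[0, 1] == pytest.approx(100.0)
        disjoint = pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 1.0]})
        assert bray_curtis(disjoint).values[0, 1] == pytest.approx(0.0)

    def test_matches_scipy(self):
        from scipy.spatial.distance import braycurtis
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        sim = bray_curtis(df)
        for i, j in itertools.combinations(range(4), 2):
            expected = 100 * (1 - braycurtis(df.iloc[:, i], df.iloc[:, j]))
            assert sim.values[i, j] == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1e3), st.floats(0, 1e3)),
                    min_size=1, max_size=20),
           st.floats(0.1, 100.0))
    def test_properties(self, rows, scale):
        x = np.array([r[0] for r in rows])
        y = np.array([r[1] for r in rows])
        if (x + y).sum() == 0:
            return
        df = pd.DataFrame({"x": x, "y": y})
        sim = bray_curtis(df)
        s = sim.values[0, 1]
        assert sim.values[1, 0] == s                      # symmetry
        assert -1e-9 <= s <= 100 + 1e-9                   # bounds
        assert sim.values[0, 0] == 100.0                  # self-similarity
        scaled = bray_curtis(df * scale)                  # scale invariance
        assert scaled.values[0, 1] == pytest.approx(s, abs=1e-6)

    def test_all_zero_pair_rejected(self):
        df = pd.DataFrame({"x": [0.0], "y": [0.0]})
        with pytest.raises(ValidationError):
            bray_curtis(df)


class TestUpgma:
    def test_two_samples(self):
        sim = SimilarityMatrix(["A", "B"], np.array([[100.0, 80], [80, 100]]))
        d = upgma(sim)
        assert d.merges == [(frozenset({"A"}), frozenset({"B"}), 80.0)]
        assert d.newick == "(A:10,B:10);"

    def test_three_sample_hand_computed(self):
        sim = SimilarityMatrix(list("ABC"), np.array(
            [[100.0, 90, 50], [90, 100, 50], [50, 50, 100]]))
        d = upgma(sim)
        assert d.merges[0][2] == pytest.approx(90.0)
        assert d.merges[1][2] == pytest.approx(50.0)   # C joins at mean(50,50)

    def test_identical_samples_merge_at_100(self):
        sim = SimilarityMatrix(list("ABC"), np.full((3, 3), 100.0))
        d = upgma(sim)
        assert all(m[2] == pytest.approx(100.0) for m in d.merges)

    def test_monotone_merge_levels_random(self):
        """Group-average linkage admits no inversions."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(3, 8)
            m = rng.random((n, n)) * 100
            m = (m + m.T) / 2
            np.fill_diagonal(m, 100.0)
            d = upgma(SimilarityMatrix([f"s{i}" for i in range(n)], m))
            levels = [mrg[2] for mrg in d.merges]
            assert all(a >= b - 1e-9 for a, b in zip(levels, levels[1:]))

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(21)
        m = rng.random((6, 6)) * 100
        m = (m + m.T) / 2
        np.fill_diagonal(m, 100.0)
        sim = SimilarityMatrix([f"s{i}" for i in range(6)], m)
        mine = sorted(100.0 - mrg[2] for mrg in upgma(sim).merges)
        scipy_heights = sorted(average(squareform(100.0 - m))[:, 2])
        assert mine == pytest.approx(scipy_heights)


class TestAnosim:
    def _sim(self, m, ids=None):
        return SimilarityMatrix(ids or [f"s{i}" for i in range(len(m))],
                                np.asarray(m, dtype=float))

    def test_perfect_separation(self):
        sim = self._sim([[100, 95, 10, 12], [95, 100, 11, 13],
                         [10, 11, 100, 96], [12, 13, 96, 100]])
        res = anosim(sim, ["g1", "g1", "g2", "g2"])
        assert res.r_statistic == pytest.approx(1.0)
        assert res.exhaustive and res.n_permutations == 6

    def test_brute_force_partitions(self):
        """R equals enumeration over the 3 distinct 2+2 partitions."""
        rng = np.random.default_rng(17)
        m = rng.random((4, 4)) * 100
        m = (m + m.T) / 2
        np.fill_diagonal(m, 100.0)
        sim = self._sim(m)
        labels = ["x", "x", "y", "y"]
        res = anosim(sim, labels)
        diss = 100.0 - m
        ranks = rankdata(diss[np.triu_indices(4, 1)])
        rm = np.zeros((4, 4))
        rm[np.triu_indices(4, 1)] = ranks
        rm += rm.T

        def brute_r(lab):
            lab = np.asarray(lab)
            iu = np.triu_indices(4, 1)
            same = (lab[:, None] == lab[None, :])[iu]
            return (rm[iu][~same].mean() - rm[iu][same].mean()) / 3.0

        assert res.r_statistic == pytest.approx(brute_r(labels))
        partitions = [["x", "x", "y", "y"], ["x", "y", "x", "y"],
                      ["x", "y", "y", "x"]]
        rs = [brute_r(p) for p in partitions]
        expected_p = np.mean([r >= res.r_statistic - 1e-12 for r in rs])
        assert res.p_value == pytest.approx(expected_p)

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim
        rng = np.random.default_rng(8)
        m = rng.random((9, 9)) * 100
        m = (m + m.T) / 2
        np.fill_diagonal(m, 100.0)
        labels = ["a"] * 5 + ["b"] * 4
        mine = anosim(self._sim(m), labels)
        sk = skbio_anosim(DistanceMatrix(100.0 - m, [f"s{i}" for i in range(9)]),
                          grouping=labels, permutations=99)
        assert mine.r_statistic == pytest.approx(sk["test statistic"])

    def test_null_r_centres_on_zero(self):
        rng = np.random.default_rng(2)
        m = rng.random((8, 8)) * 100
        m = (m + m.T) / 2
        np.fill_diagonal(m, 100.0)
        diss = 100.0 - m
        ranks = rankdata(diss[np.triu_indices(8, 1)])
        rm = np.zeros((8, 8))
        rm[np.triu_indices(8, 1)] = ranks
        rm += rm.T
        from ephygraze.community import _anosim_r, _multiset_arrangements
        rs = [_anosim_r(rm, np.asarray(p, dtype=object))
              for p in _multiset_arrangements(["a", "b"], [4, 4], 8)]
        assert np.mean(rs) == pytest.approx(0.0, abs=1e-12)

    def test_group_of_one_rejected(self):
        sim = self._sim(np.eye(3) * 100)
        with pytest.raises(ValidationError):
            anosim(sim, ["a", "a", "b"])


class TestMannWhitney:
    def test_separated_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)   # 2 of C(6,3)=20 arrangements

    def test_identical_samples(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_large_shift_enumeration(self):
        x = list(range(8))
        y = [v + 100 for v in x]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(2 / 12870)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            m, n = rng.integers(2, 6, size=2)
            x, y = rng.normal(size=m), rng.normal(size=n)  # continuous, no ties
            u, p = mann_whitney(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_normal_approx_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(0.8, 1, size=10)
        u, p = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])
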