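"""Pairwise metrics against naive oracles, exact-test identities, and
correlation/clustering structure."""

import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from interset.pairwise import (
    PairwiseMatrix,
    correlate_matrix,
    fisher_from_table,
    fisher_test,
    hierarchical_order,
    intersect_bases,
    jaccard,
    overlap_count,
    overlap_fraction,
    pairwise_matrix,
    reldist,
    write_matrix_tsv,
)
from interset.regionio import Genome, GenomicInterval, RegionSet, merge, write_bed

from oracle_utils import fisher_enumeration, naive_jaccard, naive_overlap_count, random_fixture


def _rs(label, *spans):
    return RegionSet(label, tuple(GenomicInterval(c, s, e) for c, s, e in spans))


class TestOverlap:
    def test_hand_count(self):
        a = _rs("A", ("chr1", 0, 10), ("chr1", 20, 30))
        b = _rs("B", ("chr1", 5, 6))
        assert overlap_count(a, b) == 1

    def test_self_overlap_is_merged_size(self):
        a = _rs("A", ("chr1", 0, 10), ("chr1", 5, 15), ("chr2", 0, 5))
        assert overlap_count(a, a) == len(merge(a))

    def test_empty_target(self):
        a = _rs("A", ("chr1", 0, 10))
        assert overlap_count(a, RegionSet("B")) == 0

    def test_fraction_example(self):
        a = _rs("A", ("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 40, 50))
        b = _rs("B", ("chr1", 5, 25))
        assert overlap_fraction(a, b) == pytest.approx(2 / 3, rel=1e-12)

    def test_fraction_empty_query_errors(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(RegionSet("A"), _rs("B", ("chr1", 0, 5)))


class TestJaccard:
    def test_hand_example(self):
        a, b = _rs("A", ("chr1", 0, 10)), _rs("B", ("chr1", 5, 15))
        assert jaccard(a, b) == pytest.approx(5 / 15, rel=1e-12)

    def test_self_is_one_disjoint_is_zero(self):
        a = _rs("A", ("chr1", 0, 10))
        assert jaccard(a, a) == 1.0
        assert jaccard(a, _rs("B", ("chr1", 50, 60))) == 0.0

    def test_both_empty_warns_zero(self):
        with pytest.warns(UserWarning):
            assert jaccard(RegionSet("A"), RegionSet("B")) == 0.0

    def test_matches_per_base_oracle(self):
        for seed in range(20):
            sets = random_fixture(seed)
            a, b = sets[0], sets[-1]
            assert jaccard(a, b) == pytest.approx(naive_jaccard(a, b), rel=1e-12)
            assert overlap_count(a, b) == naive_overlap_count(a, b)

    def test_agrees_with_bedtools(self, tmp_path):
        """Independent cross-check of base-pair overlap against bedtools jaccard."""
        if shutil.which("bedtools") is None:
            pytest.fail("bedtools expected on PATH in this environment")
        sets = random_fixture(1)
        a, b = merge(sets[0]), merge(sets[1])
        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(a, pa)
        write_bed(b, pb)
        out = subprocess.run(
            ["bedtools", "jaccard", "-a", str(pa), "-b", str(pb)],
            capture_output=True, text=True, check=True,
        ).stdout.splitlines()
        fields = out[1].split("\t")
        bt_inter, bt_union = int(fields[0]), int(fields[1])
        from interset.regionio import total_bases

        assert intersect_bases(a, b) == bt_inter
        assert total_bases(a) + total_bases(b) - intersect_bases(a, b) == bt_union
        assert jaccard(a, b) == pytest.approx(bt_inter / bt_union, rel=1e-12)


class TestFisher:
    def test_symmetric_table_p_one(self):
        r = fisher_from_table([[1, 1], [1, 1]])
        assert r.p_two_sided == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            t = rng.integers(0, 30, size=(2, 2))
            r = fisher_from_table(t)
            pl, pr, p2 = fisher_enumeration(t.tolist())
            assert r.p_left == pytest.approx(pl, abs=1e-9)
            assert r.p_right == pytest.approx(pr, abs=1e-9)
            assert r.p_two_sided == pytest.approx(p2, abs=1e-9)

    def test_tail_identity(self):
        """p_left + p_right exceeds 1 by exactly the observed table's mass."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            r = fisher_from_table([[a, b], [c, d]])
            p_obs = sps.hypergeom.pmf(a, a + b + c + d, a + b, a + c)
            assert r.p_left + r.p_right == pytest.approx(1.0 + p_obs, abs=1e-9)

    def test_extreme_table_infinite_odds(self):
        r = fisher_from_table([[5, 0], [0, 7]])
        assert math.isinf(r.odds_ratio)
        pl, pr, p2 = fisher_enumeration([[5, 0], [0, 7]])
        assert r.p_two_sided == pytest.approx(p2, abs=1e-9)

    def test_table_construction_from_sets(self):
        a = _rs("A", ("chr1", 0, 100), ("chr1", 200, 300))
        b = _rs("B", ("chr1", 50, 150))
        genome = Genome({"chr1": 10_000})
        r = fisher_test(a, b, genome)
        # n11 = 1 (one A interval hits B), n12 = 1, n21 = 0,
        # S = floor(2*10000 / (100 + 100)) = 100 -> n22 = 98
        assert r.table == ((1, 1), (0, 98))

    def test_missing_chromosome_named(self):
        a = _rs("A", ("chrX", 0, 10))
        with pytest.raises(ValueError, match="chrX"):
            fisher_test(a, a, Genome({"chr1": 100}))


class TestReldist:
    def test_equidistant_half(self):
        a = _rs("A", ("chr1", 45, 55))  # midpoint 50
        b = _rs("B", ("chr1", 0, 1), ("chr1", 100, 101))  # midpoints 0, 100
        assert reldist(a, b).tolist() == [0.5]

    def test_coincident_zero(self):
        a = _rs("A", ("chr1", 45, 55))
        b = _rs("B", ("chr1", 48, 52), ("chr1", 100, 140))
        assert reldist(a, b).tolist()[0] == 0.0

    def test_self_all_zero(self):
        a = _rs("A", ("chr1", 0, 10), ("chr1", 100, 110), ("chr1", 200, 220))
        assert np.all(reldist(a, a) == 0.0)

    def test_unflanked_midpoints_skipped(self):
        a = _rs("A", ("chr1", 0, 2), ("chr1", 500, 502))
        b = _rs("B", ("chr1", 100, 102), ("chr1", 200, 202))
        assert len(reldist(a, b)) == 0 or np.all((reldist(a, b) >= 0) & (reldist(a, b) <= 0.5))

    def test_values_bounded(self):
        for seed in range(10):
            sets = random_fixture(seed)
            d = reldist(sets[0], sets[-1])
            if len(d):
                assert d.min() >= 0.0 and d.max() <= 0.5


class TestPairwiseMatrix:
    def test_jaccard_identical_sets_all_ones(self):
        a = _rs("A", ("chr1", 0, 10))
        sets = [RegionSet(lab, a.intervals) for lab in "ABC"]
        m = pairwise_matrix(sets, "jaccard")
        assert np.allclose(m.values, 1.0)
        assert m.symmetric

    def test_frac_row_is_query(self):
        a = _rs("A", ("chr1", 0, 10), ("chr1", 20, 30))
        b = _rs("B", ("chr1", 0, 10))
        m = pairwise_matrix([a, b], "frac")
        assert m.values[0, 1] == pytest.approx(0.5)  # half of A's intervals hit B
        assert m.values[1, 0] == pytest.approx(1.0)
        assert np.all(np.diag(m.values) == 1.0)

    def test_jaccard_symmetry_and_order_invariance(self):
        sets = random_fixture(4)
        m = pairwise_matrix(sets, "jaccard")
        assert np.allclose(m.values, m.values.T)
        rev = pairwise_matrix(sets[::-1], "jaccard")
        assert np.allclose(rev.values, m.values[::-1, ::-1])

    def test_set_sizes_recorded(self):
        sets = random_fixture(2)
        m = pairwise_matrix(sets, "count")
        assert m.set_sizes == tuple(len(merge(s)) for s in sets)

    def test_fisher_requires_genome(self):
        with pytest.raises(ValueError, match="genome"):
            pairwise_matrix([_rs("A", ("chr1", 0, 5)), _rs("B", ("chr1", 0, 5))], "fisher")

    def test_matrix_tsv_round_shape(self, tmp_path):
        m = pairwise_matrix(random_fixture(2), "jaccard")
        path = write_matrix_tsv(m, tmp_path / "m.tsv")
        lines = open(path).read().splitlines()
        assert lines[0].split("\t")[0] == ""
        assert len(lines) == m.n + 1


class TestCorrelate:
    def _matrix(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=(4, 4))
        return PairwiseMatrix("frac", ("a", "b", "c", "d"), vals, symmetric=False)

    def test_diagonal_unit_symmetric_bounded(self):
        c = correlate_matrix(self._matrix(), "spearman")
        assert np.allclose(np.diag(c.values), 1.0)
        assert np.allclose(c.values, c.values.T)
        assert np.nanmax(np.abs(c.values)) <= 1.0 + 1e-12

    def test_spearman_matches_rank_then_pearson(self):
        m = self._matrix()
        c = correlate_matrix(m, "spearman")
        ranks = np.argsort(np.argsort(m.values, axis=0), axis=0).astype(float)
        expected = np.corrcoef(ranks, rowvar=False)
        assert np.allclose(c.values, expected, atol=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        m = self._matrix()
        c0 = correlate_matrix(m, "spearman").values
        m2 = PairwiseMatrix(m.metric, m.labels, m.values.copy(), m.symmetric)
        m2.values[:, 1] = np.exp(3 * m2.values[:, 1])  # strictly increasing
        c1 = correlate_matrix(m2, "spearman").values
        assert np.allclose(c0, c1)

    def test_zero_variance_column_warns_na(self):
        m = self._matrix()
        m.values[:, 2] = 0.7
        with pytest.warns(UserWarning, match="zero-variance"):
            c = correlate_matrix(m, "pearson")
        off_diag = [c.values[0, 2], c.values[2, 0]]
        assert np.isnan(off_diag).all()


class TestHierarchicalOrder:
    def test_identical_rows_merge_first_and_adjacent(self):
        vals = np.array([[0.0, 5.0, 5.0], [9.0, 1.0, 2.0], [9.0, 1.0, 2.0]])
        m = PairwiseMatrix("frac", ("a", "b", "c"), vals, symmetric=False)
        order, Z = hierarchical_order(m, "average", "euclidean")
        assert Z[0, 2] == 0.0
        i = order.index("b")
        assert abs(i - order.index("c")) == 1

    def test_two_rows_input_order(self):
        vals = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = PairwiseMatrix("frac", ("x", "y"), vals, symmetric=True)
        order, Z = hierarchical_order(m)
        assert order == ["x", "y"]
        assert Z.shape == (1, 4)

    def test_single_linkage_chain_heights(self):
        # four rows on a line, consecutive euclidean distance 2
        vals = np.array([[0.0], [2.0], [4.0], [6.0]]) @ np.ones((1, 4))
        vals = np.array([[0, 0, 0, 0], [2, 0, 0, 0], [4, 0, 0, 0], [6, 0, 0, 0]], dtype=float)
        m = PairwiseMatrix("frac", ("a", "b", "c", "d"), vals, symmetric=False)
        _, Z = hierarchical_order(m, "single", "euclidean")
        assert np.allclose(Z[:, 2], [2.0, 2.0, 2.0])

    def test_ward_variants_differ_but_share_topology_on_clean_data(self):
        rng = np.random.default_rng(3)
        vals = np.vstack([rng.normal(0, 0.05, (3, 6)), rng.normal(5, 0.05, (3, 6))])
        m = PairwiseMatrix("frac", tuple("abcdef"), vals, symmetric=False)
        o1, _ = hierarchical_order(m, "ward", "euclidean")
        o2, _ = hierarchical_order(m, "ward2", "euclidean")
        clusters = ({"a", "b", "c"}, {"d", "e", "f"})
        assert set(o1[:3]) in clusters
        assert set(o2[:3]) in clusters

    def test_all_methods_and_distances_run(self):
        m = pairwise_matrix(random_fixture(0), "jaccard")
        from interset.pairwise import DISTANCE_MEASURES, LINKAGE_METHODS

        for link in LINKAGE_METHODS:
            for dist in DISTANCE_MEASURES:
                order, Z = hierarchical_order(m, link, dist)
                assert sorted(order) == sorted(m.labels)
                assert Z.shape == (m.n - 1, 4)

    def test_missing_values_rejected(self):
        vals = np.array([[1.0, np.nan], [0.0, 1.0]])
        m = PairwiseMatrix("reldist", ("a", "b"), vals, symmetric=False)
        with pytest.raises(ValueError, match="missing"):
            hierarchical_order(m)
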