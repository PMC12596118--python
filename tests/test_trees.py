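"""Distances, neighbor joining, midpoint rooting, patristic distances."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from lysismine.records import SeqRecord
from lysismine.trees import (
    distance_matrix,
    midpoint_root,
    nj_tree,
    patristic_distances,
    sample_by_rank,
)

from oracles import patristic_oracle, tree_diameter_oracle


def recs(seqs, taxonomy=None):
    return [
        SeqRecord(id=f"s{i}", residues=s, alphabet="aa",
                  taxonomy=taxonomy[i] if taxonomy else None)
        for i, s in enumerate(seqs)
    ]


class TestDistances:
    def test_identical_zero(self):
        d = distance_matrix(recs(["AAAA", "AAAA", "AAAC"]))
        assert d["s0", "s1"] == 0.0

    def test_quarter_p_distance(self):
        d = distance_matrix(recs(["AAAA", "AAAC", "CCCC"]))
        assert d["s0", "s1"] == pytest.approx(0.25)

    def test_poisson_closed_form(self):
        d = distance_matrix(recs(["AAAA", "AAAC", "AACC"]), model="poisson")
        assert d["s0", "s1"] == pytest.approx(-np.log(0.75))

    def test_poisson_saturated_pair_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            distance_matrix(recs(["AAAA", "AAAC", "CCCC"]), model="poisson")

    def test_gap_columns_pairwise_deleted(self):
        d = distance_matrix(recs(["AA-A", "AACA", "AAAA"]))
        assert d["s0", "s1"] == 0.0  # gapped column dropped for that pair

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            distance_matrix(recs(["AA", "AA"]))


def random_tree_with_lengths(n, rng):
    from lysismine.synth import _random_tree

    return _random_tree([f"L{i:02d}" for i in range(n)], rng)


class TestNJ:
    def test_four_taxon_additive_recovery(self):
        from skbio import DistanceMatrix

        # tree ((a,b),(c,d)) with internal edge 3
        d = DistanceMatrix(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
            ["a", "b", "c", "d"],
        )
        t = nj_tree(d)
        tips = {frozenset(t.name for t in clade.tips()) for clade in t.non_tips()}
        assert frozenset({"a", "b"}) in tips or frozenset({"c", "d"}) in tips

    def test_three_taxon_closed_form(self):
        from skbio import DistanceMatrix

        d = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        t = nj_tree(d)
        pat = t.tip_tip_distances()
        assert pat["a", "b"] == pytest.approx(3.0)
        assert pat["a", "c"] == pytest.approx(4.0)
        assert pat["b", "c"] == pytest.approx(5.0)

    def test_additive_matrices_recover_topology(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            true = random_tree_with_lengths(n, rng)
            d = true.tip_tip_distances()
            est = nj_tree(d)
            assert est.compare_rfd(true) == 0.0

    def test_asymmetric_matrix_rejected(self):
        from skbio import DistanceMatrix

        with pytest.raises(Exception):
            bad = np.array([[0, 1.0, 2], [1.1, 0, 1], [2, 1, 0]])
            nj_tree(DistanceMatrix(bad, ["a", "b", "c"], validate=False))


class TestMidpoint:
    def test_two_leaf_bisection(self):
        t = TreeNode.read(io.StringIO("(a:3,b:1);"))
        rooted = midpoint_root(t)
        depths = {tip.name: tip.accumulate_to_ancestor(rooted) for tip in rooted.tips()}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_matches_diameter_bisection_on_random_trees(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = random_tree_with_lengths(8, rng)
            diameter, a, b = tree_diameter_oracle(t)
            rooted = midpoint_root(t.copy())
            depths = {tip.name: tip.accumulate_to_ancestor(rooted) for tip in rooted.tips()}
            assert max(depths.values()) == pytest.approx(diameter / 2)
            assert depths[a] == pytest.approx(diameter / 2) or depths[b] == pytest.approx(diameter / 2)

    def test_zero_length_tree_rejected(self):
        t = TreeNode.read(io.StringIO("(a:0,b:0);"))
        with pytest.raises(ValueError):
            midpoint_root(t)


class TestPatristic:
    def test_pendant_sum(self):
        t = TreeNode.read(io.StringIO("(a:1,b:2);"))
        assert patristic_distances(t)["a", "b"] == pytest.approx(3.0)

    def test_matches_path_summation_oracle(self):
        rng = np.random.default_rng(2)
        t = random_tree_with_lengths(10, rng)
        d = patristic_distances(t)
        for (a, b), expected in patristic_oracle(t).items():
            assert d[a, b] == pytest.approx(expected)


class TestRankSampling:
    def taxed(self, spec):
        # spec: list of (genus, length)
        return [
            SeqRecord(id=f"s{i}", residues="A" * ln, alphabet="aa",
                      taxonomy=("domain:Bacteria", f"genus:{g}"))
            for i, (g, ln) in enumerate(spec)
        ]

    def test_one_representative_per_genus(self):
        seqs = self.taxed([("X", 10), ("X", 20), ("Y", 5), ("Y", 5), ("X", 15)])
        reps = sample_by_rank(seqs)
        assert len(reps) == 2

    def test_longest_wins_ties_by_id(self):
        seqs = self.taxed([("X", 10), ("X", 20), ("X", 20)])
        reps = sample_by_rank(seqs)
        assert reps[0].id == "s1"  # longest, smallest id among ties

    def test_missing_rank_raises(self):
        seqs = [SeqRecord(id="s", residues="AA", alphabet="aa", taxonomy=("domain:B",))]
        with pytest.raises(ValueError):
            sample_by_rank(seqs)
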