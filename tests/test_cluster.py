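"""Dereplication, greedy clustering, MCL and similarity networks."""

import networkx as nx
import numpy as np
import pytest

from lysismine.cluster import (
    build_similarity_network,
    dedup_exact,
    greedy_cluster,
    mcl_cluster,
)
from lysismine.records import SeqRecord
from lysismine.synth import mutate_sequence

from oracles import mcl_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def recs(seqs):
    return [SeqRecord(id=f"s{i:03d}", residues=s, alphabet="aa") for i, s in enumerate(seqs)]


class TestDedup:
    def test_identical_collapse(self):
        cs = dedup_exact(recs(["AAA", "AAA", "AAC"]))
        assert cs.n_clusters == 2

    def test_all_distinct(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(AA), size=30)) for _ in range(25)]
        assert dedup_exact(recs(seqs)).n_clusters == 25

    def test_planted_duplicates(self):
        """100 sequences with 17 planted duplicates collapse to 83."""
        rng = np.random.default_rng(1)
        base = ["".join(rng.choice(list(AA), size=40)) for _ in range(83)]
        dups = [base[i % 83] for i in range(17)]
        cs = dedup_exact(recs(base + dups))
        assert cs.n_clusters == 83

    def test_representative_is_smallest_id(self):
        cs = dedup_exact(recs(["PPP", "PPP"]))
        assert set(cs.assignment.values()) == {"s000"}


class TestGreedy:
    def test_identical_join(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        assert greedy_cluster(recs([seq, seq])).n_clusters == 1

    def test_unrelated_random_separate(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list(AA), size=200))
        b = "".join(rng.choice(list(AA), size=200))
        from lysismine.align import pairwise_align

        pair = recs([a, b])
        assert pairwise_align(pair[0], pair[1]).identity < 0.5
        assert greedy_cluster(pair).n_clusters == 2

    def test_divergent_mutant_joins_at_half_identity(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list(AA), size=150))
        b = mutate_sequence(a, 0.3, seed=5)
        assert greedy_cluster(recs([a, b])).n_clusters == 1

    def test_strict_thresholds_reduce_to_dedup(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list(AA), size=50)) for _ in range(10)]
        seqs += seqs[:4]  # duplicates
        members = recs(seqs)
        strict = greedy_cluster(members, min_identity=1.0, min_coverage=1.0)
        exact = dedup_exact(members)
        strict_parts = {frozenset(v) for v in strict.clusters.values()}
        exact_parts = {frozenset(v) for v in exact.clusters.values()}
        assert strict_parts == exact_parts


class TestMCL:
    def test_two_cliques(self):
        g = nx.Graph()
        for offset in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(offset + i, offset + j, weight=1.0)
        assert mcl_cluster(g).n_clusters == 2

    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_node("c")
        cs = mcl_cluster(g)
        assert cs.assignment["c"] == "c"
        assert cs.n_clusters == 2

    def test_barbell_matches_independent_fixed_point(self):
        g = nx.Graph()
        for tri in ((0, 1, 2), (3, 4, 5)):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(tri[i], tri[j], weight=1.0)
        g.add_edge(2, 3, weight=1.0)
        cs = mcl_cluster(g, inflation=2.0)
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        oracle = mcl_oracle(adj, inflation=2.0)
        ours = sorted(
            (sorted(int(m) for m in members) for members in cs.clusters.values()),
            key=lambda s: s[0],
        )
        assert ours == [sorted(s) for s in oracle]

    def test_clusters_never_span_components(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(1000)))
            nx.set_edge_attributes(g, 1.0, "weight")
            cs = mcl_cluster(g)
            comp_of = {}
            for k, comp in enumerate(nx.connected_components(g)):
                for n in comp:
                    comp_of[n] = k
            for members in cs.clusters.values():
                assert len({comp_of[m] for m in members}) == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.Graph())


class TestNetwork:
    def test_identical_triplet_forms_clique(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        g = build_similarity_network(recs([seq] * 3), min_identity=0.5)
        assert g.number_of_edges() == 3
        assert all(d["weight"] == pytest.approx(1.0) for _, _, d in g.edges(data=True))

    def test_unrelated_proteins_edgeless(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list(AA), size=120)) for _ in range(4)]
        g = build_similarity_network(recs(seqs), min_identity=0.5)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 4

    def test_symmetry_by_construction(self):
        rng = np.random.default_rng(7)
        a = "".join(rng.choice(list(AA), size=80))
        b = mutate_sequence(a, 0.2, seed=8)
        g = build_similarity_network(recs([a, b]), min_identity=0.5)
        assert g.has_edge("s000", "s001") and g.has_edge("s001", "s000")
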