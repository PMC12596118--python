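"""Dereplication, greedy identity clustering, Markov clustering, and
protein similarity networks.

``greedy_cluster`` mirrors the behaviour of length-sorted greedy clustering
tools (representatives are the longest members; a sequence joins the first
representative it matches at the identity/coverage thresholds).
``mcl_cluster`` is a direct implementation of Markov clustering: add
self-loops, column-normalize, then alternate expansion (matrix squaring)
and inflation (entrywise power + renormalization) to a fixed point; clusters
are the connected components of the limit matrix's support.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .align import pairwise_align
from .records import SeqRecord, check_unique_ids


@dataclass
class ClusterSet:
    """A partition of member ids with one representative per cluster."""

    assignment: dict[str, str]  # member id -> cluster (representative) id

    def __post_init__(self) -> None:
        reps = set(self.assignment.values())
        for rep in reps:
            if rep not in self.assignment:
                raise ValueError(f"representative {rep!r} is not a member")

    @property
    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for member, rep in sorted(self.assignment.items()):
            out.setdefault(rep, []).append(member)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def representatives(self) -> list[str]:
        return sorted(set(self.assignment.values()))


def dedup_exact(seqs: list[SeqRecord]) -> ClusterSet:
    """Collapse byte-identical sequences; representative = smallest id."""
    check_unique_ids(seqs)
    by_residues: dict[str, list[str]] = {}
    for s in seqs:
        by_residues.setdefault(s.residues, []).append(s.id)
    assignment: dict[str, str] = {}
    for ids in by_residues.values():
        rep = min(ids)
        for i in ids:
            assignment[i] = rep
    return ClusterSet(assignment)


def greedy_cluster(
    seqs: list[SeqRecord],
    min_identity: float = 0.50,
    min_coverage: float = 0.90,
) -> ClusterSet:
    """Length-sorted greedy clustering at identity/coverage thresholds.

    Sequences are visited in order of decreasing length (ties by id); each
    joins the first existing cluster whose representative it matches at
    >= min_identity with >= min_coverage on both sequences, else founds one.
    """
    check_unique_ids(seqs)
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    reps: list[SeqRecord] = []
    assignment: dict[str, str] = {}
    for s in ordered:
        placed = False
        for rep in reps:
            aln = pairwise_align(s, rep)
            if (
                aln.identity >= min_identity
                and aln.coverage_query >= min_coverage
                and aln.coverage_target >= min_coverage
            ):
                assignment[s.id] = rep.id
                placed = True
                break
        if not placed:
            reps.append(s)
            assignment[s.id] = s.id
    return ClusterSet(assignment)


# ---------------------------------------------------------------------------
# Similarity networks


def build_similarity_network(
    seqs: list[SeqRecord],
    min_identity: float = 0.0,
    attributes: dict[str, dict] | None = None,
) -> nx.Graph:
    """All-vs-all identity network: every protein is a node (source and
    target); an undirected edge carries the identity when it meets the
    threshold. Self-comparisons are excluded."""
    check_unique_ids(seqs)
    g = nx.Graph()
    for s in seqs:
        g.add_node(s.id, **(attributes.get(s.id, {}) if attributes else {}))
    ordered = sorted(seqs, key=lambda s: s.id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            ident = max(
                pairwise_align(a, b).identity,
                pairwise_align(b, a).identity,
            )
            if ident >= min_identity and ident > 0:
                g.add_edge(a.id, b.id, weight=ident)
    return g


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tolerance: float = 1e-8,
    prune: float = 1e-6,
) -> ClusterSet:
    """Markov clustering of a weighted undirected graph."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    np.fill_diagonal(m, np.maximum(m.diagonal(), 1.0))  # self-loops
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        inflated = inflated / inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tolerance:
            m = inflated
            break
        m = inflated
    else:
        raise RuntimeError(f"MCL did not converge in {max_iter} iterations")
    # attractor components: nodes connected through the limit support
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 0)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    assignment: dict[str, str] = {}
    for comp in nx.connected_components(support):
        members = sorted(nodes[i] for i in comp)
        rep = members[0]
        for member in members:
            assignment[member] = rep
    return ClusterSet(assignment)
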