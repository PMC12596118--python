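"""Horizontal-gene-transfer candidate selection and direction inference.

Candidate clusters are built from an all-vs-all identity graph (viral-viral
edges at >= 95% identity, edges involving a bacterial protein at >= 90%),
Markov-clustered at inflation 2.0, and kept when both sources contribute at
least two members.  Direction is read off the midpoint-rooted tree: when
one source forms a clade nested inside a paraphyletic grade of the other,
the grade is the donor and the nested clade the recipient; any other
configuration is left unresolved — with near-identical sequences and no
outgroup, that is the honest answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from skbio import TreeNode

from .align import pairwise_align
from .cluster import mcl_cluster
from .records import SeqRecord


@dataclass
class HGTEvent:
    cluster_id: str
    status: str  # "resolved" or "unresolved"
    donor: str | None = None  # source tag of the donor grade
    recipients: tuple[str, ...] = ()  # leaf names of the nested clade

    def __post_init__(self) -> None:
        if self.status == "resolved" and self.donor is None:
            raise ValueError("resolved event needs a donor")


def select_hgt_clusters(
    seqs: list[SeqRecord],
    viral_viral_min: float = 0.95,
    viral_bact_min: float = 0.90,
    inflation: float = 2.0,
    min_per_source: int = 2,
) -> list[list[str]]:
    """MCL clusters of the thresholded identity graph with >= 2 members
    from each source (viral and bacterial)."""
    tags = {s.id: s.source for s in seqs}
    g = nx.Graph()
    g.add_nodes_from(tags)
    ordered = sorted(seqs, key=lambda s: s.id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            ident = pairwise_align(a, b).identity
            threshold = (
                viral_viral_min
                if tags[a.id] == "viral" and tags[b.id] == "viral"
                else viral_bact_min
            )
            if ident >= threshold:
                g.add_edge(a.id, b.id, weight=ident)
    clusters = mcl_cluster(g, inflation=inflation)
    kept = []
    for rep, members in sorted(clusters.clusters.items()):
        n_viral = sum(1 for m in members if tags[m] == "viral")
        n_bact = sum(1 for m in members if tags[m] == "bacterial")
        if n_viral >= min_per_source and n_bact >= min_per_source:
            kept.append(sorted(members))
    return kept


def _is_monophyletic(tree: TreeNode, names: set[str]) -> bool:
    tips = [t for t in tree.tips() if t.name in names]
    if len(tips) != len(names):
        raise ValueError("leaves missing from tree")
    if len(tips) == 1:
        return True
    lca = tree.lca(tips)
    return {t.name for t in lca.tips()} == names


def infer_hgt_direction(
    tree: TreeNode,
    tags: dict[str, str],
    cluster_id: str = "cluster",
) -> HGTEvent:
    """Donor/recipient from a midpoint-rooted, source-tagged tree.

    Exactly one source monophyletic -> that source is the nested recipient
    clade and the paraphyletic other source is the donor.  Both or neither
    monophyletic -> unresolved.
    """
    leaf_names = {t.name for t in tree.tips()}
    untagged = leaf_names - set(tags)
    if untagged:
        raise ValueError(f"untagged leaves: {sorted(untagged)[:5]}")
    sources = sorted({tags[n] for n in leaf_names})
    if len(sources) != 2:
        return HGTEvent(cluster_id=cluster_id, status="unresolved")
    groups = {s: {n for n in leaf_names if tags[n] == s} for s in sources}
    mono = {s: _is_monophyletic(tree, groups[s]) for s in sources}
    if sum(mono.values()) != 1:
        return HGTEvent(cluster_id=cluster_id, status="unresolved")
    recipient = next(s for s in sources if mono[s])
    donor = next(s for s in sources if not mono[s])
    return HGTEvent(
        cluster_id=cluster_id,
        status="resolved",
        donor=donor,
        recipients=tuple(sorted(groups[recipient])),
    )
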