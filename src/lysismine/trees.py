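"""Distance-based trees: p/Poisson distances, neighbor joining, midpoint
rooting, patristic distances, and rank-level representative sampling.

Trees are scikit-bio ``TreeNode`` objects throughout; leaf source tags
(viral / bacterial / archaeal) travel in a separate mapping keyed by leaf
name.  Neighbor joining stands in for likelihood inference at desk scale;
on additive matrices it provably recovers the generating topology.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .records import SeqRecord


def distance_matrix(seqs: list[SeqRecord], model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances from an aligned protein set.

    p-distance = mismatches / compared columns under pairwise deletion of
    gapped columns; Poisson = -ln(1 - p).
    """
    if len(seqs) < 3:
        raise ValueError("need >= 3 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    ids = [s.id for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i].residues, seqs[j].residues
            pairs = [(x, y) for x, y in zip(a, b) if x not in "-." and y not in "-."]
            if not pairs:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            p = sum(1 for x, y in pairs if x != y) / len(pairs)
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("saturated pair: p-distance of 1")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining; negative branch lengths are clamped to
    zero with the deficit moved to the adjacent edge."""
    if d.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(d.data, d.data.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return nj(d, neg_as_zero=True)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    total = sum(n.length or 0.0 for n in tree.traverse() if not n.is_root())
    if total <= 0:
        raise ValueError("cannot midpoint-root a tree with zero total length")
    tips = list(tree.tips())
    if len(tips) == 2:  # degenerate: bisect the single path directly
        half = total / 2.0
        root = TreeNode()
        for tip in tips:
            root.append(TreeNode(name=tip.name, length=half))
        return root
    return tree.root_at_midpoint()


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances."""
    return tree.tip_tip_distances()


def rank_value(record: SeqRecord, rank: str) -> str:
    """Extract a rank's value from a 'rank:value' taxonomy path."""
    if record.taxonomy is None:
        raise ValueError(f"record {record.id!r} has no taxonomy")
    prefix = rank + ":"
    for entry in record.taxonomy:
        if entry.startswith(prefix):
            return entry[len(prefix) :]
    raise ValueError(f"record {record.id!r} lacks rank {rank!r}")


def sample_by_rank(seqs: list[SeqRecord], rank: str = "genus", seed: int = 0) -> list[SeqRecord]:
    """One representative per rank value: the longest sequence, ties by id.

    The choice is deterministic; ``seed`` is accepted for interface
    stability with the stochastic samplers.
    """
    groups: dict[str, list[SeqRecord]] = {}
    for s in seqs:
        groups.setdefault(rank_value(s, rank), []).append(s)
    reps = []
    for value in sorted(groups):
        reps.append(min(groups[value], key=lambda s: (-len(s), s.id)))
    return reps
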