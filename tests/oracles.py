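"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (plain loops, no reuse of
the package's algorithm code) so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def glocal_score_oracle(
    a: str,
    b: str,
    open_cost: float = 11.0,
    extend_cost: float = 1.0,
) -> float:
    """Optimal overlap (free-end-gap) affine alignment score, quadratic DP."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = 0.0  # free leading gap
    for j in range(1, m + 1):
        Iy[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_BLOSUM62[a[i - 1], b[j - 1]])
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - extend_cost)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - extend_cost)
    best = NEG
    for i in range(n + 1):  # free trailing gaps
        best = max(best, M[i][m], Ix[i][m], Iy[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], Ix[n][j], Iy[n][j])
    return best


def tmr_scan_oracle(
    protein: str,
    kd: dict[str, float],
    window: int = 19,
    threshold: float = 1.6,
    min_gap: int = 5,
) -> list[tuple[int, int]]:
    """Plain window-scan transmembrane segment oracle (center convention)."""
    if len(protein) < window:
        return []
    half = window // 2
    centers = []
    for c in range(half, len(protein) - half):
        w = protein[c - half : c + half + 1]
        if sum(kd[x] for x in w) / window >= threshold:
            centers.append(c)
    runs: list[list[int]] = []
    for c in centers:
        if runs and c - runs[-1][1] <= 1:
            runs[-1][1] = c
        else:
            runs.append([c, c])
    merged: list[list[int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] - 1 < min_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(max(0, s - half), min(len(protein), e + half + 1)) for s, e in merged]


def mcl_oracle(adjacency: np.ndarray, inflation: float = 2.0, iters: int = 300) -> list[set[int]]:
    """Independent fixed-point Markov clustering on a dense matrix."""
    m = adjacency.astype(float).copy()
    for i in range(m.shape[0]):
        m[i, i] = max(m[i, i], 1.0)
    m = m / m.sum(axis=0)
    for _ in range(iters):
        m2 = np.linalg.matrix_power(m, 2) ** inflation
        m2 = m2 / m2.sum(axis=0)
        if np.abs(m2 - m).max() < 1e-12:
            m = m2
            break
        m = m2
    n = m.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows, cols = np.nonzero(m > 1e-9)
    for r, c in zip(rows, cols):
        ra, rb = find(int(r)), find(int(c))
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda s: min(s))


def patristic_oracle(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf distances by explicit root-path summation."""
    paths = {}
    for tip in tree.tips():
        path = {}
        node, acc = tip, 0.0
        while node.parent is not None:
            acc += node.length or 0.0
            node = node.parent
            path[id(node)] = acc
        paths[tip.name] = path
    out = {}
    names = sorted(paths)
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            shared = [k for k in paths[x] if k in paths[y]]
            best = min(paths[x][k] + paths[y][k] for k in shared)
            out[(x, y)] = best
    return out


def tree_diameter_oracle(tree) -> tuple[float, str, str]:
    """Longest tip-to-tip path by brute force."""
    dists = patristic_oracle(tree)
    (a, b), d = max(dists.items(), key=lambda kv: kv[1])
    return d, a, b
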