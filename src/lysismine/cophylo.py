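"""Procrustes (PACo) and fourth-corner (ParaFit) cophylogeny tests.

Both tests start from patristic distance matrices of the two trees, apply
the Cailliez correction (the smallest additive constant making the
off-diagonal distances Euclidean-embeddable), embed by classical principal
coordinates, and assess congruence of the association-linked point pairs by
permutation (default 999, +1 smoothing):

* PACo: m2_XY = residual sum of squares of the Procrustes superposition of
  the dependent configuration onto the other; small m2 = congruent, so the
  p-value counts permuted m2 <= observed.
* ParaFit: ParaFitGlobal = sum of squares of the fourth-corner matrix
  C' A' B (B, C the two coordinate matrices, A the association incidence);
  large values = congruent, so the p-value counts permuted >= observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .trees import patristic_distances


@dataclass
class CophylogenyResult:
    statistic_name: str  # "m2_XY" or "ParaFitGlobal"
    observed: float
    n_permutations: int
    p_value: float
    correction: str = "cailliez"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value out of (0, 1]")


def cailliez_constant(d: np.ndarray) -> float:
    """Smallest c such that d + c (off-diagonal) is Euclidean-embeddable.

    Standard construction: the largest real eigenvalue of the 2n x 2n block
    matrix [[0, 2*delta1], [-I, -4*delta2]] with delta1 = -D^2/2 centered and
    delta2 = -D/2 centered.
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    delta1 = j @ (-0.5 * d**2) @ j
    delta2 = j @ (-0.5 * d) @ j
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eigvals = np.linalg.eigvals(np.vstack([upper, lower]))
    c = max(0.0, float(np.max(eigvals.real)))
    return c


def cailliez_correct(d: np.ndarray) -> np.ndarray:
    c = cailliez_constant(d)
    if c == 0.0:
        return d.copy()
    out = d + c
    np.fill_diagonal(out, 0.0)
    return out


def pcoa_coords(d: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Classical principal-coordinate embedding, positive axes only."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eps * max(1.0, vals.max() if len(vals) else 1.0)
    if not keep.any():
        raise ValueError("degenerate embedding: no positive eigenvalues")
    return vecs[:, keep] * np.sqrt(vals[keep])


def _embed_trees(
    tree_a: TreeNode, tree_b: TreeNode, association: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Association-ordered PCoA coordinates (Cailliez-corrected) for both trees."""
    if not association:
        raise ValueError("empty association")
    da: DistanceMatrix = patristic_distances(tree_a)
    db: DistanceMatrix = patristic_distances(tree_b)
    a_leaves = sorted(association)
    b_leaves = [association[a] for a in a_leaves]
    if len(set(b_leaves)) != len(b_leaves):
        raise ValueError("association must be one-to-one")
    xa = pcoa_coords(cailliez_correct(da.filter(a_leaves).data))
    xb = pcoa_coords(cailliez_correct(db.filter(b_leaves).data))
    return xa, xb


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Residual SS after optimal translation/rotation/scaling of y onto x."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    ssx = (xc**2).sum()
    ssy = (yc**2).sum()
    if ssx == 0 or ssy == 0:
        raise ValueError("degenerate configuration")
    sv = np.linalg.svd(xc.T @ yc, compute_uv=False)
    trace = sv.sum()
    return max(0.0, float(ssx - trace**2 / ssy))


def paco_test(
    tree_a: TreeNode,
    tree_b: TreeNode,
    association: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> CophylogenyResult:
    """PACo Procrustes congruence test with permutation p-value."""
    xa, xb = _embed_trees(tree_a, tree_b, association)
    observed = _procrustes_m2(xa, xb)
    rng = np.random.default_rng(seed)
    n = xa.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _procrustes_m2(xa, xb[perm]) <= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return CophylogenyResult("m2_XY", observed, n_perm, p)


def _parafit_global(xa: np.ndarray, xb: np.ndarray) -> float:
    # identity association after row-matching: A = I, so D = xb' xa
    return float(((xb.T @ xa) ** 2).sum())


def parafit_test(
    tree_a: TreeNode,
    tree_b: TreeNode,
    association: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> CophylogenyResult:
    """ParaFit global congruence test with permutation p-value."""
    xa, xb = _embed_trees(tree_a, tree_b, association)
    observed = _parafit_global(xa, xb)
    rng = np.random.default_rng(seed)
    n = xa.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _parafit_global(xa, xb[perm]) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return CophylogenyResult("ParaFitGlobal", observed, n_perm, p)
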