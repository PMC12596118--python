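"""Rarefaction of protein clusters, saturation assessment, genome-size
correlation, and network degree statistics."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from scipy.special import gammaln


@dataclass
class RarefactionCurve:
    sizes: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    reps: int
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.sizes) > 0):
            raise ValueError("sample sizes must be strictly increasing")


@dataclass
class StatResult:
    name: str
    value: float | None
    p_value: float | None = None
    n: int = 0
    flag: str | None = None


def rarefaction_curve(
    items: dict[str, str],
    max_n: int | None = None,
    step: int = 500,
    reps: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Mean distinct-cluster count among n items sampled without
    replacement, for n = step, 2*step, ... up to max_n (truncated to the
    item count), over ``reps`` replicates."""
    if not items:
        raise ValueError("empty item set")
    if step < 1:
        raise ValueError("step must be >= 1")
    members = sorted(items)
    labels = sorted(set(items.values()))
    label_idx = {c: i for i, c in enumerate(labels)}
    assign = np.array([label_idx[items[m]] for m in members])
    total = len(members)
    if max_n is None or max_n > total:
        max_n = total
    sizes = np.arange(step, max_n + 1, step)
    if len(sizes) == 0 or sizes[-1] != max_n:
        sizes = np.append(sizes, max_n)
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for n in sizes:
        counts = []
        for _ in range(reps):
            sample = rng.choice(total, size=int(n), replace=False)
            counts.append(len(np.unique(assign[sample])))
        counts = np.array(counts, dtype=float)
        means.append(counts.mean())
        sds.append(counts.std(ddof=0))
    return RarefactionCurve(
        sizes=sizes.astype(int), means=np.array(means), sds=np.array(sds), reps=reps, seed=seed
    )


def expected_distinct_clusters(cluster_sizes: np.ndarray, n: int) -> float:
    """Closed-form hypergeometric expectation of distinct clusters in a
    sample of n items: sum_k (1 - C(N - N_k, n) / C(N, n))."""
    total = int(cluster_sizes.sum())
    if not (0 <= n <= total):
        raise ValueError("n out of range")
    expect = 0.0
    for nk in cluster_sizes:
        # C(N - nk, n) / C(N, n) via log-gammas for stability
        if total - nk < n:
            expect += 1.0
            continue
        logp = (
            gammaln(total - nk + 1)
            - gammaln(n + 1)
            - gammaln(total - nk - n + 1)
            - (gammaln(total + 1) - gammaln(n + 1) - gammaln(total - n + 1))
        )
        expect += 1.0 - np.exp(logp)
    return float(expect)


def saturation_slope(
    curve: RarefactionCurve,
    tail_fraction: float = 0.2,
    epsilon: float = 0.001,
) -> StatResult:
    """Least-squares slope of the curve tail, normalized by the final
    cluster count; 'saturated' when below epsilon new clusters per item."""
    if len(curve.sizes) < 5:
        raise ValueError("need >= 5 curve points")
    k = max(2, int(np.ceil(tail_fraction * len(curve.sizes))))
    x = curve.sizes[-k:].astype(float)
    y = curve.means[-k:]
    slope = float(np.polyfit(x, y, 1)[0])
    total = curve.means[-1] if curve.means[-1] > 0 else 1.0
    normalized = slope / total
    return StatResult(
        name="saturation_slope",
        value=normalized,
        n=k,
        flag="saturated" if slope < epsilon else "not saturated",
    )


def genome_size_correlation(
    sizes: dict[str, int],
    copy_numbers: dict[str, dict[str, int]],
) -> dict[str, StatResult]:
    """Pearson correlation of genome size vs per-type lytic-gene copy
    number, one result per lytic type; zero-variance inputs are flagged."""
    genomes = sorted(sizes)
    if len(genomes) < 3:
        raise ValueError("need >= 3 genomes")
    if set(copy_numbers) - set(sizes):
        raise ValueError("copy numbers for unknown genomes")
    types = sorted({t for counts in copy_numbers.values() for t in counts})
    x = np.array([sizes[g] for g in genomes], dtype=float)
    out = {}
    for t in types:
        y = np.array([copy_numbers.get(g, {}).get(t, 0) for g in genomes], dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[t] = StatResult(name=f"pearson_r[{t}]", value=None, n=len(genomes), flag="degenerate")
            continue
        r, p = stats.pearsonr(x, y)
        out[t] = StatResult(name=f"pearson_r[{t}]", value=float(r), p_value=float(p), n=len(genomes))
    return out


def degree_stats(graph: nx.Graph, category_attr: str | None = None) -> dict[str, StatResult]:
    """Average degree (2|E|/|V|), optionally per node category."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    avg = 2.0 * graph.number_of_edges() / graph.number_of_nodes()
    out = {"all": StatResult(name="average_degree", value=avg, n=graph.number_of_nodes())}
    if category_attr is not None:
        by_cat: dict[str, list[int]] = {}
        for node, data in graph.nodes(data=True):
            by_cat.setdefault(data.get(category_attr, "unknown"), []).append(graph.degree(node))
        for cat in sorted(by_cat):
            degs = by_cat[cat]
            out[cat] = StatResult(
                name=f"average_degree[{cat}]", value=float(np.mean(degs)), n=len(degs)
            )
    return out
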