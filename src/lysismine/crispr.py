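"""CRT-style CRISPR array detection, spacer-protospacer matching, and
host-range statistics.

Array detection follows the seed-and-extend scheme of repeat-recognition
tools: exact words of length ``searchWL`` recurring at array-like spacing
seed candidate repeats, whose boundaries are then extended while *all*
instances agree on the flanking nucleotide (unanimity extension).  Repeats
inside one array are therefore exact copies — degenerate repeats are out of
scope.  Spacer matching is ungapped on both strands ("SNP" semantics), with
the published filters: >= 95% identity, >= 95% coverage, <= 1 mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import SeqRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class CrisprArray:
    genome_id: str
    repeat: str  # consensus = the repeated word itself
    repeat_positions: list[tuple[int, int]]  # 0-based half-open, ordered
    spacers: list[tuple[str, int, int]]  # (sequence, start, end)

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.repeat_positions) - 1:
            raise ValueError("spacer count must be repeat count - 1")
        for (s1, e1), (s2, e2) in zip(self.repeat_positions, self.repeat_positions[1:]):
            if e1 > s2:
                raise ValueError("overlapping repeats")

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def mean_spacer_length(self) -> float:
        return float(np.mean([e - s for _, s, e in self.spacers]))


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    virus_id: str
    strand: str
    position: int  # forward-strand start of the protospacer
    mismatches: int
    identity: float
    coverage: float


def detect_arrays(
    genome: SeqRecord,
    minRL: int = 20,
    maxRL: int = 50,
    minSL: int = 20,
    maxSL: int = 60,
    searchWL: int = 7,
) -> list[CrisprArray]:
    """Detect exact-repeat CRISPR arrays (>= 2 repeats) in a genome."""
    seq = genome.residues.upper()
    n = len(seq)
    if n <= minRL + minSL:
        raise ValueError("genome too short for array detection")
    lo, hi = minRL + minSL, maxRL + maxSL

    positions: dict[str, list[int]] = {}
    for i in range(n - searchWL + 1):
        positions.setdefault(seq[i : i + searchWL], []).append(i)

    seen: set[tuple] = set()
    arrays: list[CrisprArray] = []
    for word in sorted(positions):
        occs = positions[word]
        if len(occs) < 2:
            continue
        # maximal chains of occurrences at array-like spacing
        chains: list[list[int]] = []
        current = [occs[0]]
        for prev, cur in zip(occs, occs[1:]):
            if lo <= cur - prev <= hi:
                current.append(cur)
            else:
                if len(current) >= 2:
                    chains.append(current)
                current = [cur]
        if len(current) >= 2:
            chains.append(current)
        for chain in chains:
            arr = _extend_chain(seq, chain, searchWL, minRL, maxRL, minSL, maxSL, genome.id)
            if arr is None:
                continue
            key = (tuple(arr.repeat_positions),)
            if key not in seen:
                seen.add(key)
                arrays.append(arr)
    # seed words colliding with nearby background can chain truncated
    # variants of one array; keep only the maximal array per genomic span
    arrays.sort(key=lambda a: (-len(a.repeat_positions), -len(a.repeat), a.repeat_positions[0]))
    accepted: list[CrisprArray] = []
    for arr in arrays:
        span = (arr.repeat_positions[0][0], arr.repeat_positions[-1][1])
        if any(
            span[0] < acc.repeat_positions[-1][1] and acc.repeat_positions[0][0] < span[1]
            for acc in accepted
        ):
            continue
        accepted.append(arr)
    accepted.sort(key=lambda a: a.repeat_positions[0])
    return accepted


def _extend_chain(
    seq: str,
    occs: list[int],
    word_len: int,
    minRL: int,
    maxRL: int,
    minSL: int,
    maxSL: int,
    genome_id: str,
) -> CrisprArray | None:
    """Unanimity extension of a seed chain to full repeat boundaries."""
    left = 0
    while True:
        cand = left + 1
        if occs[0] - cand < 0 or word_len + cand > maxRL:
            break
        flank = {seq[o - cand] for o in occs}
        if len(flank) != 1:
            break
        left = cand
    right = 0
    while True:
        cand = right + 1
        if occs[-1] + word_len + cand > len(seq) or word_len + left + cand > maxRL:
            break
        flank = {seq[o + word_len + right] for o in occs}
        if len(flank) != 1:
            break
        right = cand
    rep_len = word_len + left + right
    if not (minRL <= rep_len <= maxRL):
        return None
    starts = [o - left for o in occs]
    # keep the longest run whose spacers are within bounds
    best_run: list[int] = []
    run = [starts[0]]
    for prev, cur in zip(starts, starts[1:]):
        spacer_len = cur - (prev + rep_len)
        if minSL <= spacer_len <= maxSL:
            run.append(cur)
        else:
            if len(run) > len(best_run):
                best_run = run
            run = [cur]
    if len(run) > len(best_run):
        best_run = run
    if len(best_run) < 2:
        return None
    repeat = seq[best_run[0] : best_run[0] + rep_len]
    repeat_positions = [(s, s + rep_len) for s in best_run]
    spacers = []
    for (s1, e1), (s2, _) in zip(repeat_positions, repeat_positions[1:]):
        spacers.append((seq[e1:s2], e1, s2))
    return CrisprArray(genome_id, repeat, repeat_positions, spacers)


def filter_arrays(
    arrays: list[CrisprArray],
    ratio_min: float = 0.6,
    ratio_max: float = 2.5,
    min_spacers: int = 3,
) -> list[CrisprArray]:
    """Published array filters: mean spacer/repeat length ratio in
    [0.6, 2.5] and at least three spacers."""
    kept = []
    for a in arrays:
        if a.n_spacers < min_spacers:
            continue
        ratio = a.mean_spacer_length / len(a.repeat)
        if ratio_min <= ratio <= ratio_max:
            kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# Spacer-protospacer matching


def _best_ungapped(spacer: str, genome: str) -> tuple[int, int] | None:
    """(mismatches, position) of the best ungapped placement, or None."""
    k = len(spacer)
    if k > len(genome):
        return None
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    s = np.frombuffer(spacer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(g, k)
    mism = (windows != s).sum(axis=1)
    pos = int(np.argmin(mism))
    return int(mism[pos]), pos


def match_spacers(
    spacers: dict[str, str],
    viral_genomes: list[SeqRecord],
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
    max_snp: int = 1,
) -> list[SpacerMatch]:
    """Ungapped scan of both strands; best accepted hit per (spacer, genome).

    Matches are full-length placements of the spacer (coverage 1.0); a hit
    is accepted when mismatches <= max_snp and identity >= min_identity.
    """
    for sid, s in spacers.items():
        if len(s) < 20:
            raise ValueError(f"spacer {sid!r} shorter than 20 nt")
    matches = []
    for genome in sorted(viral_genomes, key=lambda g: g.id):
        fwd = genome.residues.upper()
        rev = _revcomp(fwd)
        for sid in sorted(spacers):
            sp = spacers[sid].upper()
            k = len(sp)
            cands = []
            hit = _best_ungapped(sp, fwd)
            if hit is not None:
                cands.append((hit[0], "+", hit[1]))
            hit = _best_ungapped(sp, rev)
            if hit is not None:
                cands.append((hit[0], "-", len(fwd) - hit[1] - k))
            if not cands:
                continue
            mism, strand, pos = min(cands)
            identity = (k - mism) / k
            if mism <= max_snp and identity >= min_identity and 1.0 >= min_coverage:
                matches.append(
                    SpacerMatch(
                        spacer_id=sid,
                        virus_id=genome.id,
                        strand=strand,
                        position=pos,
                        mismatches=mism,
                        identity=identity,
                        coverage=1.0,
                    )
                )
    return matches


# ---------------------------------------------------------------------------
# Host assignment and range


def host_assignments(
    matches: list[SpacerMatch],
    spacer_host_species: dict[str, str],
) -> dict[str, set[str]]:
    """virus id -> set of host species supported by accepted matches."""
    out: dict[str, set[str]] = {}
    for m in matches:
        species = spacer_host_species[m.spacer_id]
        out.setdefault(m.virus_id, set()).add(species)
    return out


def host_range(
    assignments: dict[str, set[str]],
    all_viruses: list[str] | None = None,
) -> dict[str, int]:
    """Distinct host species count per virus (0 for unmatched viruses)."""
    viruses = all_viruses if all_viruses is not None else sorted(assignments)
    return {v: len(assignments.get(v, set())) for v in viruses}


def subsample_host_range(
    assignments: dict[str, set[str]],
    taxonomy: dict[str, str],  # species -> phylum
    phylum_quota: int = 100,
    special_quotas: dict[str, int] | None = None,
    reps: int = 10,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Phylum-quota subsampled host range, averaged over replicates.

    In each replicate, phyla with at least their quota of distinct species
    are downsampled to the quota (``special_quotas`` override the default
    per named phylum); host range is recomputed on the sampled species.
    Returns per-virus mean host range, plus the group label when given.
    """
    if phylum_quota <= 0:
        raise ValueError("quota must be positive")
    special_quotas = special_quotas or {}
    all_species = sorted({s for ss in assignments.values() for s in ss})
    missing = [s for s in all_species if s not in taxonomy]
    if missing:
        raise KeyError(f"taxonomy missing species: {missing[:5]}")
    by_phylum: dict[str, list[str]] = {}
    for s in all_species:
        by_phylum.setdefault(taxonomy[s], []).append(s)
    rng = np.random.default_rng(seed)
    viruses = sorted(assignments)
    counts = np.zeros((reps, len(viruses)))
    for r in range(reps):
        sampled: set[str] = set()
        for phylum in sorted(by_phylum):
            pool = by_phylum[phylum]
            quota = special_quotas.get(phylum, phylum_quota)
            if len(pool) >= quota:
                sampled.update(rng.choice(pool, size=quota, replace=False))
            else:
                sampled.update(pool)
        for j, v in enumerate(viruses):
            counts[r, j] = len(assignments[v] & sampled)
    df = pd.DataFrame(
        {
            "virus_id": viruses,
            "mean_host_range": counts.mean(axis=0),
            "sd_host_range": counts.std(axis=0, ddof=0),
        }
    )
    if groups is not None:
        df["group"] = [groups.get(v, "ungrouped") for v in viruses]
    return df
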