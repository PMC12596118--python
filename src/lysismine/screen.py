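"""Candidate discovery: keyword screening, provirus masking, pooling.

Four discovery routes feed the classifier: (1) profile search of annotated
proteins, (2) keyword screening of annotation strings, (3) keyword screening
of re-annotated gene calls, (4) profile search of re-predicted ORFs.  The
pooling step unions candidates by genomic location and records which routes
found each one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import GeneCall

DEFAULT_KEYWORDS = (
    "endolysin",
    "lysin",
    "lysozyme",
    "holin",
    "spanin",
    "rz1",
    "rz",
    "muramidase",
    "amidase",
    "peptidase",
    "transglycosylase",
    "pseudomurein endoisopeptidase",
    "protein e",
    "pyramid",
)
DEFAULT_VETO = ("tail", "baseplate", "structural")

# keyword -> candidate lytic type (first match wins, checked in this order)
KEYWORD_TYPES = (
    ("endolysin", "endolysin"),
    ("lysozyme", "endolysin"),
    ("muramidase", "endolysin"),
    ("amidase", "endolysin"),
    ("transglycosylase", "endolysin"),
    ("pseudomurein endoisopeptidase", "Pei"),
    ("peptidase", "endolysin"),
    ("lysin", "endolysin"),
    ("holin", "holin"),
    ("spanin", "spanin"),
    ("rz1", "spanin"),
    ("rz", "spanin"),
    ("protein e", "pE"),
    ("pyramid", "PVAP"),
)


def keyword_screen(
    annotations: dict[str, str],
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
    veto: tuple[str, ...] = DEFAULT_VETO,
) -> list[str]:
    """Case-insensitive substring screen of annotation strings.

    Negative keywords veto a description before positives are considered
    (a "tail lysozyme" is a structural protein, not an endolysin).
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    hits = []
    for pid in sorted(annotations):
        desc = annotations[pid].lower()
        if any(v.lower() in desc for v in veto):
            continue
        if any(k.lower() in desc for k in keywords):
            hits.append(pid)
    return hits


def keyword_type(description: str) -> str | None:
    """Candidate lytic type implied by an annotation string, or None."""
    desc = description.lower()
    if any(v in desc for v in DEFAULT_VETO):
        return None
    for key, lytic_type in KEYWORD_TYPES:
        if key in desc:
            return lytic_type
    return None


# ---------------------------------------------------------------------------
# Provirus masking


@dataclass(frozen=True)
class MaskReport:
    excluded_genes: tuple[str, ...]
    short_fragments: tuple[tuple[int, int], ...]  # regions < min_fragment


def mask_proviral(
    genes: list[GeneCall],
    regions: list[tuple[int, int]],
    genome_length: int,
    min_fragment: int = 4000,
) -> tuple[list[GeneCall], MaskReport]:
    """Drop genes overlapping any predicted provirus region.

    Every predicted region masks the host gene set regardless of its size;
    regions shorter than ``min_fragment`` are additionally flagged as short
    fragments and discarded from the viral side of the analysis.
    """
    for s, e in regions:
        if not (0 <= s < e <= genome_length):
            raise ValueError(f"provirus interval [{s},{e}) outside genome of {genome_length} nt")
    kept, excluded = [], []
    for g in genes:
        if any(g.start < e and s < g.end for s, e in regions):
            excluded.append(g.gene_id)
        else:
            kept.append(g)
    short = tuple((s, e) for s, e in regions if e - s < min_fragment)
    return kept, MaskReport(excluded_genes=tuple(excluded), short_fragments=short)


# ---------------------------------------------------------------------------
# Pooling


@dataclass
class Candidate:
    """A lytic-protein candidate keyed by genomic location."""

    genome_id: str
    start: int
    end: int
    strand: str
    protein: str
    protein_id: str
    lytic_type: str | None = None
    routes: set[int] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.genome_id, self.start, self.end, self.strand)


def merge_pipelines(route_candidates: dict[int, list[Candidate]]) -> list[Candidate]:
    """Union candidates from the discovery routes by (genome, coords, strand),
    recording provenance. Conflicting translations at one location raise."""
    merged: dict[tuple, Candidate] = {}
    for route in sorted(route_candidates):
        for cand in route_candidates[route]:
            key = cand.key
            if key in merged:
                existing = merged[key]
                if existing.protein != cand.protein:
                    raise ValueError(
                        f"conflicting translations at {key}: routes "
                        f"{sorted(existing.routes)} vs {route}"
                    )
                existing.routes.add(route)
                if existing.lytic_type is None:
                    existing.lytic_type = cand.lytic_type
            else:
                merged[key] = Candidate(
                    genome_id=cand.genome_id,
                    start=cand.start,
                    end=cand.end,
                    strand=cand.strand,
                    protein=cand.protein,
                    protein_id=cand.protein_id,
                    lytic_type=cand.lytic_type,
                    routes={route},
                )
    return [merged[k] for k in sorted(merged)]
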