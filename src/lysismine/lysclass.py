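"""QC rules and subclass assignment for lytic proteins.

Endolysins are rejected when they carry virion-associated (structural)
domains, transmembrane regions, or no recognizable catalytic / binding
domain; survivors are labelled by catalytic category (amidase, muramidase,
endopeptidase, transglycosylase, glucosaminidase), ``m-EAD`` when two or
more distinct catalytic categories co-occur, ``s-CBD`` when only a binding
domain is present, and ``unclassified`` when the catalytic category is
unrecognized.  Holins are classed by transmembrane-segment count (TMRs-1 to
TMRs-4, with a dedicated TMRs-4+ flag).  Spanin complexes are typed by gene
geometry (separated / embedded / overlapping / unimolecular) after checking
that the inner component carries a TMR and the outer a lipobox.

Transmembrane regions are predicted from Kyte-Doolittle hydropathy with a
19-residue window and a 1.6 threshold — the canonical settings for TM
segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import re

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

EAD_CATEGORIES = {
    "glucosaminidase",
    "transglycosylase",
    "endopeptidase",
    "muramidase",
    "amidase",
}
CATEGORIES = EAD_CATEGORIES | {"CBD", "VAL-structural", "other"}

ENDOLYSIN_SUBCLASSES = EAD_CATEGORIES | {"s-CBD", "m-EAD", "unclassified"}
HOLIN_SUBCLASSES = {"TMRs-1", "TMRs-2", "TMRs-3", "TMRs-4", "TMRs-4+"}
SPANIN_SUBCLASSES = {"SOS", "SIS", "EOS", "EIS", "OOS", "OIS", "USP"}

LIPOBOX_RE = re.compile(r"[LVIMFT][ASTVIG][GAS]C")


@dataclass(frozen=True)
class DomainHit:
    family: str
    category: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown domain category {self.category!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("bad domain span")


@dataclass(frozen=True)
class TMRSegment:
    start: int
    end: int
    mean_hydropathy: float


@dataclass
class LypRecord:
    protein_id: str
    lytic_type: str
    subclass: str | None
    verdict: str  # "pass" or "reject:<reason>"
    provenance: tuple[int, ...] = ()

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


# ---------------------------------------------------------------------------
# Feature prediction


def predict_tmrs(
    protein: str,
    window: int = 19,
    hydropathy_threshold: float = 1.6,
    min_gap: int = 5,
) -> list[TMRSegment]:
    """Kyte-Doolittle sliding-window TMR prediction.

    Window means are assigned to center positions; maximal runs of centers
    with mean >= threshold become segments, and segments separated by fewer
    than ``min_gap`` residues are merged.  Proteins shorter than the window
    yield no segments.
    """
    if len(protein) < window:
        return []
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")  # centers window//2 .. len-window//2-1
    half = window // 2
    above = means >= hydropathy_threshold
    segments: list[list[int]] = []
    for i, flag in enumerate(above):
        center = i + half
        if flag:
            if segments and center - segments[-1][1] <= 1:
                segments[-1][1] = center
            else:
                segments.append([center, center])
    merged: list[list[int]] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] - 1 < min_gap:
            merged[-1][1] = seg[1]
        else:
            merged.append(seg)
    out = []
    for s, e in merged:
        lo = max(0, s - half)
        hi = min(len(protein), e + half + 1)
        out.append(
            TMRSegment(start=lo, end=hi, mean_hydropathy=float(values[lo:hi].mean()))
        )
    return out


def detect_lipobox(protein: str, scan_window: int = 40) -> int | None:
    """Position of the lipobox cysteine in the N-terminal scan window,
    or None.  Pattern: [LVIMFT][ASTVIG][GAS]C with Cys index < scan_window."""
    m = LIPOBOX_RE.search(protein[: scan_window + 3])
    if m is None:
        return None
    cys = m.start() + 3
    return cys if cys < scan_window else None


# ---------------------------------------------------------------------------
# Classifiers


def classify_endolysin(
    protein_id: str,
    domains: Sequence[DomainHit],
    tmrs: Sequence[TMRSegment],
    provenance: tuple[int, ...] = (),
) -> LypRecord:
    """Endolysin QC + subclass from domain content and TMRs."""
    if any(d.category == "VAL-structural" for d in domains):
        return LypRecord(protein_id, "endolysin", None, "reject:VAL", provenance)
    if tmrs:
        return LypRecord(protein_id, "endolysin", None, "reject:TMR", provenance)
    ead = sorted({d.category for d in domains if d.category in EAD_CATEGORIES})
    other = [d for d in domains if d.category == "other"]
    cbd = [d for d in domains if d.category == "CBD"]
    if not ead and not cbd and not other:
        return LypRecord(protein_id, "endolysin", None, "reject:no-domain", provenance)
    if len(ead) >= 2:
        subclass = "m-EAD"
    elif len(ead) == 1:
        subclass = ead[0]
    elif other:
        subclass = "unclassified"
    else:
        subclass = "s-CBD"
    return LypRecord(protein_id, "endolysin", subclass, "pass", provenance)


def classify_holin(
    protein_id: str,
    tmrs: Sequence[TMRSegment],
    provenance: tuple[int, ...] = (),
) -> LypRecord:
    """Holin QC + TMR-count subclass."""
    k = len(tmrs)
    if k == 0:
        return LypRecord(protein_id, "holin", None, "reject:no-TMR", provenance)
    subclass = f"TMRs-{k}" if k <= 4 else "TMRs-4+"
    return LypRecord(protein_id, "holin", subclass, "pass", provenance)


@dataclass
class SpaninComponent:
    protein_id: str
    start: int
    end: int
    strand: str
    protein: str


@dataclass
class SpaninComplex:
    """One or two co-located spanin genes plus derived per-component features."""

    components: list[SpaninComponent]

    def __post_init__(self) -> None:
        if len(self.components) not in (1, 2):
            raise ValueError("a spanin complex has one or two components")

    @property
    def arrangement(self) -> str:
        if len(self.components) == 1:
            return "unimolecular"
        (a, b) = sorted(self.components, key=lambda c: (c.start, c.end))
        if a.end <= b.start:
            return "separated"
        if a.start <= b.start and b.end <= a.end:
            return "embedded"
        return "overlapping"


_ARRANGEMENT_LABELS = {
    "separated": ("SIS", "SOS"),
    "embedded": ("EIS", "EOS"),
    "overlapping": ("OIS", "OOS"),
}


def classify_spanin(
    complex_: SpaninComplex,
    provenance: tuple[int, ...] = (),
) -> list[LypRecord]:
    """QC and label a spanin complex; one record per component.

    Inner component = the TMR carrier, outer = the lipobox carrier; when
    features do not disambiguate, the upstream gene is taken as inner
    (the natural i-spanin/o-spanin gene order).  A unimolecular spanin
    needs both features with the lipobox N-terminal of the C-terminal TMR.
    """
    comps = complex_.components
    feats = []
    for c in comps:
        feats.append((predict_tmrs(c.protein), detect_lipobox(c.protein)))

    if complex_.arrangement == "unimolecular":
        (tmrs, lipo) = feats[0]
        pid = comps[0].protein_id
        if not tmrs:
            return [LypRecord(pid, "spanin", None, "reject:no-TMR", provenance)]
        if lipo is None:
            return [LypRecord(pid, "spanin", None, "reject:no-lipobox", provenance)]
        last_tmr = max(t.start for t in tmrs)
        if lipo >= last_tmr:
            return [LypRecord(pid, "spanin", None, "reject:no-lipobox", provenance)]
        return [LypRecord(pid, "spanin", "USP", "pass", provenance)]

    ordered = sorted(range(2), key=lambda i: (comps[i].start, comps[i].end))
    has_tmr = [bool(feats[i][0]) for i in range(2)]
    has_lipo = [feats[i][1] is not None for i in range(2)]
    if has_tmr[ordered[0]] != has_tmr[ordered[1]]:
        inner = ordered[0] if has_tmr[ordered[0]] else ordered[1]
    elif has_lipo[ordered[0]] != has_lipo[ordered[1]]:
        inner = ordered[1] if has_lipo[ordered[0]] else ordered[0]
    else:
        inner = ordered[0]  # gene order fallback
    outer = 1 - inner

    inner_label, outer_label = _ARRANGEMENT_LABELS[complex_.arrangement]
    records = []
    if has_tmr[inner]:
        records.append(LypRecord(comps[inner].protein_id, "spanin", inner_label, "pass", provenance))
    else:
        records.append(LypRecord(comps[inner].protein_id, "spanin", None, "reject:no-TMR", provenance))
    if has_lipo[outer]:
        records.append(LypRecord(comps[outer].protein_id, "spanin", outer_label, "pass", provenance))
    else:
        records.append(LypRecord(comps[outer].protein_id, "spanin", None, "reject:no-lipobox", provenance))
    return records


# ---------------------------------------------------------------------------
# Genome-level composition


def summarize_lysis_systems(
    records: Iterable[LypRecord],
    protein_genome: dict[str, str],
) -> pd.DataFrame:
    """Per-genome lysis-system combination from QC-passing records.

    Returns a table with one row per genome: the sorted '&'-joined set of
    lytic types present ("none" for genomes with no passing record) and the
    per-type counts.
    """
    by_genome: dict[str, list[LypRecord]] = {g: [] for g in set(protein_genome.values())}
    for r in records:
        if not r.passed:
            continue
        genome = protein_genome.get(r.protein_id)
        if genome is None:
            raise KeyError(f"no genome for protein {r.protein_id!r}")
        by_genome[genome].append(r)
    rows = []
    for genome in sorted(by_genome):
        recs = by_genome[genome]
        types = sorted({r.lytic_type for r in recs})
        combo = " & ".join(types) if types else "none"
        counts: dict[str, int] = {}
        for r in recs:
            counts[r.lytic_type] = counts.get(r.lytic_type, 0) + 1
        rows.append({"genome_id": genome, "combination": combo, **counts})
    df = pd.DataFrame(rows).fillna(0)
    count_cols = [c for c in df.columns if c not in ("genome_id", "combination")]
    df[count_cols] = df[count_cols].astype(int)
    return df


def combination_proportions(summary: pd.DataFrame) -> pd.Series:
    """Fraction of genomes per lysis-system combination (sums to 1)."""
    return summary["combination"].value_counts(normalize=True)
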