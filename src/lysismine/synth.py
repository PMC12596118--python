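"""Synthetic viral/host genome generator with planted lysis systems.

The generator is the study-conditions module: it emits viral genomes whose
genes carry exactly the features the downstream screen and classifier look
for (domain motifs, hydrophobic transmembrane blocks, lipobox motifs,
spanin gene-pair geometries), host genomes with CRISPR arrays whose spacers
copy viral protospacers at controlled mismatch counts, homolog sets at
controlled divergence for transfer scenarios, and tree pairs at controlled
incongruence — all recorded in a truth table keyed to every downstream
assertion.

Composition is deliberately stylized for analytical tractability:
backgrounds are i.i.d. uniform nucleotides, non-membrane protein regions
are drawn from a 13-letter polar alphabet (Kyte-Doolittle <= -0.4, no Cys)
so that no accidental transmembrane segment or lipobox can arise, and
transmembrane blocks are 21 consecutive residues from {L,I,V,F,A} separated
by >= 30 strongly polar residues so the window-19 hydropathy detector finds
exactly the planted count.  Overlapping and embedded spanin pairs are laid
out on the same strand in the +1 reading frame (the lambda Rz/Rz1
arrangement), with codon choices retried until the inner frame reads
through cleanly.  Mutations are exact-count (not per-site Bernoulli) so
identity thresholds are noise-free.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from skbio import TreeNode

from .records import GeneCall, SeqRecord

SCAFFOLD_AA = "DEGHKNPQRSTWY"  # polar, no Cys, KD <= -0.4
STRONG_POLAR = "DEKNQR"  # KD <= -3.5: linker windows stay far below threshold
TMR_AA = "AFILV"
NT = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_table11 = CodonTable.unambiguous_dna_by_id[11]
CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_table11.forward_table.items()):
    CODONS[_aa] = CODONS.get(_aa, ()) + (_codon,)
STOP_CODONS = tuple(sorted(_table11.stop_codons))


# ---------------------------------------------------------------------------
# Motif vocabulary


@dataclass(frozen=True)
class MotifFamily:
    family: str
    motif: str
    category: str  # domain category fed to the classifier
    lytic_type: str  # candidate type implied by a hit of this family


@dataclass
class MotifVocabulary:
    """Domain families: consensus motif, catalytic category, lytic type."""

    families: dict[str, MotifFamily]

    def __post_init__(self) -> None:
        for fam in self.families.values():
            if not (12 <= len(fam.motif) <= 30):
                raise ValueError(f"{fam.family}: motif length out of 12-30")
            if set(fam.motif) - set(AA20):
                raise ValueError(f"{fam.family}: non-canonical residues")

    def by_category(self, category: str) -> list[MotifFamily]:
        return [f for f in self.families.values() if f.category == category]


_VOCAB_PLAN = [
    ("Ami2_like", "amidase", "endolysin"),
    ("Ami3_like", "amidase", "endolysin"),
    ("GH24_like", "muramidase", "endolysin"),
    ("SLT_like", "transglycosylase", "endolysin"),
    ("M23_like", "endopeptidase", "endolysin"),
    ("GH73_like", "glucosaminidase", "endolysin"),
    ("LysM_CBD", "CBD", "endolysin"),
    ("EAD_X", "other", "endolysin"),
    ("VAL_gp5", "VAL-structural", "endolysin"),
    ("PeiA_like", "endopeptidase", "Pei"),
    ("pE_like", "other", "pE"),
    ("PVAP_like", "other", "PVAP"),
]


def default_vocabulary(motif_len: int = 24) -> MotifVocabulary:
    """The fixed default vocabulary: one polar-composition consensus motif
    per family, deterministic across sessions."""
    rng = np.random.default_rng(941159)
    fams = {}
    for name, category, lytic_type in _VOCAB_PLAN:
        motif = "".join(rng.choice(list(SCAFFOLD_AA), size=motif_len))
        fams[name] = MotifFamily(name, motif, category, lytic_type)
    if len({f.motif for f in fams.values()}) != len(fams):
        raise RuntimeError("vocabulary motifs not unique")
    return MotifVocabulary(fams)


# ---------------------------------------------------------------------------
# Low-level sequence builders


def _rand_aa(rng: np.random.Generator, n: int, alphabet: str = SCAFFOLD_AA) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n > 0 else ""


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NT), size=n)) if n > 0 else ""


def _tmr_block(rng: np.random.Generator) -> str:
    return _rand_aa(rng, 21, TMR_AA)


def _linker(rng: np.random.Generator, n: int = 30) -> str:
    return _rand_aa(rng, n, STRONG_POLAR)


def _codons(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate; the initiator is always ATG."""
    parts = ["ATG"]
    for aa in protein[1:]:
        parts.append(str(rng.choice(CODONS[aa])))
    return "".join(parts)


def _gene_nt(protein: str, rng: np.random.Generator) -> str:
    return _codons(protein, rng) + "TAA"


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_REVCOMP)[::-1]


def _translate11(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append("*" if codon in STOP_CODONS else _table11.forward_table[codon])
    return "".join(out)


def mutate_sequence(seq: str, divergence: float, seed: int, alphabet: str | None = None) -> str:
    """Substitute exactly round(divergence * len) positions to a different
    symbol; length preserved."""
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must be in [0, 1]")
    if alphabet is None:
        alphabet = NT if set(seq) <= set(NT) else AA20
    rng = np.random.default_rng(seed)
    k = round(divergence * len(seq))
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [c for c in alphabet if c != out[pos]]
        out[pos] = str(rng.choice(choices))
    return "".join(out)


# ---------------------------------------------------------------------------
# Planted gene plans


@dataclass
class PlantedGene:
    """One element to plant.

    kind: endolysin | holin | spanin_pair | usp | pE | Pei | PVAP | background
    reject: None for a clean gene, else the expected QC failure
    ("TMR", "VAL", "no-domain", "no-TMR", "no-lipobox").
    """

    kind: str
    families: tuple[str, ...] = ()  # endolysin domain plan
    tmr_count: int = 2  # holins
    arrangement: str = "separated"  # spanin pairs
    reject: str | None = None


@dataclass
class GenomePlan:
    genes: list[PlantedGene]
    n_background: int = 3


@dataclass
class PlantSpec:
    plans: list[GenomePlan]
    genome_length: tuple[int, int] = (9_000, 20_000)
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return len(self.plans)


@dataclass
class TruthRow:
    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    lytic_type: str | None  # None for background genes
    subclass: str | None
    verdict: str | None  # expected QC verdict for lytic genes
    partner_id: str | None = None


@dataclass
class SyntheticDataset:
    genomes: list[SeqRecord]
    gene_calls: list[GeneCall]
    annotations: dict[str, str]  # gene id -> description
    truth: list[TruthRow]
    vocabulary: MotifVocabulary

    @property
    def proteins(self) -> dict[str, str]:
        return {c.gene_id: c.protein for c in self.gene_calls}

    def truth_lytic(self) -> list[TruthRow]:
        return [r for r in self.truth if r.lytic_type is not None]


_ANNOTATIONS = {
    "endolysin": "putative endolysin",
    "holin": "phage holin",
    "spanin_inner": "Rz-like spanin",
    "spanin_outer": "Rz1 spanin",
    "usp": "unimolecular spanin",
    "pE": "cell lysis protein E",
    "Pei": "pseudomurein endoisopeptidase",
    "PVAP": "virus-associated pyramid protein",
    "background": "hypothetical protein",
}


# ---------------------------------------------------------------------------
# Protein builders (single-gene kinds)


def _endolysin_protein(
    gene: PlantedGene, vocab: MotifVocabulary, rng: np.random.Generator
) -> tuple[str, str | None, str]:
    from .lysclass import EAD_CATEGORIES

    parts = ["M", _rand_aa(rng, 40)]
    if gene.reject == "no-domain":
        parts.append(_rand_aa(rng, 60))
        return "".join(parts), None, "reject:no-domain"
    fams = [vocab.families[f] for f in gene.families]
    for fam in fams:
        parts.append(fam.motif)
        parts.append(_rand_aa(rng, 15))
    parts.append(_rand_aa(rng, 20))
    if gene.reject == "TMR":
        parts.append(_tmr_block(rng))
        parts.append(_rand_aa(rng, 8))
        return "".join(parts), None, "reject:TMR"
    if any(f.category == "VAL-structural" for f in fams):
        return "".join(parts), None, "reject:VAL"
    cats = sorted({f.category for f in fams if f.category in EAD_CATEGORIES})
    if len(cats) >= 2:
        subclass = "m-EAD"
    elif len(cats) == 1:
        subclass = cats[0]
    elif any(f.category == "other" for f in fams):
        subclass = "unclassified"
    else:
        subclass = "s-CBD"
    return "".join(parts), subclass, "pass"


def _holin_protein(gene: PlantedGene, rng: np.random.Generator) -> tuple[str, str | None, str]:
    k = 0 if gene.reject == "no-TMR" else gene.tmr_count
    if k == 0:
        return "M" + _rand_aa(rng, 60), None, "reject:no-TMR"
    parts = ["M", _linker(rng, 6)]
    for _ in range(k):
        parts.append(_tmr_block(rng))
        parts.append(_linker(rng))
    subclass = f"TMRs-{k}" if k <= 4 else "TMRs-4+"
    return "".join(parts), subclass, "pass"


def _outer_spanin_protein(rng: np.random.Generator, lipobox: bool = True, length: int = 58) -> str:
    body = list("M" + _rand_aa(rng, length - 1))
    if lipobox:
        body[15:19] = "LAGC"  # Cys at index 18, inside the 40-residue scan
    return "".join(body)


def _inner_spanin_protein(rng: np.random.Generator, tmr: bool = True, length: int = 105) -> str:
    head = "M" + _rand_aa(rng, 4)
    block = _tmr_block(rng) if tmr else _rand_aa(rng, 21)
    return head + block + _rand_aa(rng, length - len(head) - len(block))


def _usp_protein(rng: np.random.Generator, reject: str | None) -> tuple[str, str | None, str]:
    lipo = reject != "no-lipobox"
    tmr = reject != "no-TMR"
    body = list("M" + _rand_aa(rng, 45))
    if lipo:
        body[15:19] = "LAGC"
    protein = "".join(body) + (_tmr_block(rng) if tmr else _rand_aa(rng, 21)) + _rand_aa(rng, 12)
    if not tmr:
        return protein, None, "reject:no-TMR"
    if not lipo:
        return protein, None, "reject:no-lipobox"
    return protein, "USP", "pass"


def _accessory_protein(gene: PlantedGene, vocab: MotifVocabulary, rng: np.random.Generator) -> str:
    fam = vocab.families[gene.families[0]] if gene.families else vocab.families[
        {"pE": "pE_like", "Pei": "PeiA_like", "PVAP": "PVAP_like"}[gene.kind]
    ]
    return "M" + _rand_aa(rng, 20) + fam.motif + _rand_aa(rng, 20)


# ---------------------------------------------------------------------------
# Same-strand frame-shifted spanin pair loci

# In the +1 frame, inner codon = prev_codon[2] + cur_codon[0:2]; a stop
# (TAA/TAG/TGA) therefore needs prev ending 'T' and cur starting AA/AG/GA.
_BAD_PREFIXES = ("AA", "AG", "GA")
_AA_FORCED_START = ("D", "E", "K", "N")  # every codon starts with a bad prefix


def _o_codons_safe(
    o_protein: list[str], rng: np.random.Generator, forced: dict[int, str]
) -> list[str]:
    """Synonymous codons for the outer gene that keep the inner (+1 shifted)
    frame free of unintended stop codons.

    Rules: never end a codon with 'T' when the next codon is bound to start
    with AA/AG/GA (residues D/E/K/N, or a forced codon that does); when the
    previous codon ends with 'T', avoid codons starting with AA/AG/GA.
    Both rules are always satisfiable for the alphabets used here.
    """
    codons: list[str] = ["ATG"]
    for idx in range(1, len(o_protein)):
        if idx in forced:
            codons.append(forced[idx])
            continue
        nxt_bad = False
        if idx + 1 < len(o_protein):
            if idx + 1 in forced:
                nxt_bad = forced[idx + 1][:2] in _BAD_PREFIXES
            else:
                nxt_bad = o_protein[idx + 1] in _AA_FORCED_START
        prev_t = codons[-1][-1] == "T"
        options = list(CODONS[o_protein[idx]])
        rng.shuffle(options)
        pick = None
        for c in options:
            if nxt_bad and c[-1] == "T":
                continue
            if prev_t and c[:2] in _BAD_PREFIXES:
                continue
            pick = c
            break
        if pick is None:
            raise RuntimeError(f"no safe codon for residue {o_protein[idx]!r} at {idx}")
        codons.append(pick)
    return codons


def _nested_pair_nt(
    o_protein: str,
    rng: np.random.Generator,
    overlapping: bool,
    i_protein_len: int = 150,
    max_tries: int = 1000,
) -> tuple[str, str, str, int, int, int]:
    """Lay an outer-spanin gene in the +1 frame of an inner-spanin gene.

    Returns (locus_nt, inner_protein, outer_protein, o_start, i_nt_len,
    o_nt_len); the outer protein may differ from the request at the two
    residues that spell the inner gene's stop codon in the overlapping
    arrangement.
    Embedded: the outer gene sits fully inside the inner interval.
    Overlapping: the inner gene's stop codon lies inside the outer gene, so
    the intervals intersect without containment.
    """
    o_protein = list(o_protein)
    i_nt_len = 3 * i_protein_len + 3
    o_nt_len = 3 * len(o_protein) + 3
    if overlapping:
        r = 23  # i's stop starts this many nt after o's start
        q = i_nt_len - 3 - r
        # force o residues whose codons can spell TAA in the inner frame
        t = (r - 2) // 3  # o codon index ending 1 nt before i's stop
        o_protein[t] = "N"  # AAT
        o_protein[t + 1] = "K"  # AAA: the inner frame reads ...T|AA... = stop
    else:
        q = 3 * 50 + 1
        if q + o_nt_len > i_nt_len - 3:
            raise ValueError("inner gene too short to embed the outer gene")
    if q % 3 != 1:
        raise AssertionError("outer gene must sit in the +1 frame")
    head = "M" + _rand_aa(rng, 4) + _tmr_block(rng)
    n_prefix_aa = (q - 1) // 3
    if n_prefix_aa < len(head):
        raise ValueError("inner gene too short for its transmembrane head")

    forced = {t: "AAT", t + 1: "AAA"} if overlapping else {}
    for _ in range(max_tries):
        o_codons = _o_codons_safe(o_protein, rng, forced)
        o_nt = "".join(o_codons) + str(rng.choice(STOP_CODONS))
        prefix = _codons(head + _rand_aa(rng, n_prefix_aa - len(head)), rng)
        joint = str(rng.choice(list(NT)))
        core = prefix + joint + o_nt  # o starts exactly at q
        if overlapping:
            locus = core
            i_nt = core[:i_nt_len]
        else:
            tail_len = i_nt_len - 3 - len(core)
            tail = _rand_nt(rng, 2) if tail_len >= 2 else ""
            # complete the mid-codon junction safely, then polar codons
            if tail_len >= 2:
                tail = "CC" + "".join(
                    str(rng.choice(CODONS[aa])) for aa in _rand_aa(rng, (tail_len - 2) // 3)
                )
                tail += _rand_nt(rng, tail_len - len(tail))
            i_nt = core + tail + "TAA"
            locus = i_nt
        aa = _translate11(i_nt)
        if "*" in aa[:-1] or aa[-1] != "*":
            continue
        inner_protein = "M" + aa[1:-1]
        return locus, inner_protein, "".join(o_protein), q, i_nt_len, o_nt_len
    raise RuntimeError("could not lay out frame-shifted spanin pair")


# ---------------------------------------------------------------------------
# Locus assembly


@dataclass
class _Locus:
    nt: str
    genes: list[tuple[str, int, int, str, str]]  # (role, start, end, strand, protein)
    truth: list[TruthRow] = field(default_factory=list)  # coords relative to locus


def _spanin_pair_locus(
    gene: PlantedGene, genome_id: str, gid: callable, rng: np.random.Generator
) -> _Locus:
    arrangement = gene.arrangement
    if arrangement == "separated":
        i_rej = gene.reject == "no-TMR"
        o_rej = gene.reject == "no-lipobox"
        ip = _inner_spanin_protein(rng, tmr=not i_rej)
        op = _outer_spanin_protein(rng, lipobox=not o_rej)
        i_nt = _gene_nt(ip, rng)
        o_nt = _gene_nt(op, rng)
        gap = _rand_nt(rng, int(rng.integers(20, 60)))
        nt = i_nt + gap + o_nt
        i_id, o_id = gid(), gid()
        genes = [
            ("spanin_inner", 0, len(i_nt), "+", ip),
            ("spanin_outer", len(i_nt) + len(gap), len(nt), "+", op),
        ]
        truth = [
            TruthRow(genome_id, i_id, 0, len(i_nt), "+", "spanin",
                     None if i_rej else "SIS", "reject:no-TMR" if i_rej else "pass", o_id),
            TruthRow(genome_id, o_id, len(i_nt) + len(gap), len(nt), "+", "spanin",
                     None if o_rej else "SOS", "reject:no-lipobox" if o_rej else "pass", i_id),
        ]
        return _Locus(nt, genes, truth)
    if arrangement in ("embedded", "overlapping"):
        locus_nt, ip, op, q, i_nt_len, o_nt_len = _nested_pair_nt(
            _outer_spanin_protein(rng), rng, overlapping=(arrangement == "overlapping")
        )
        i_id, o_id = gid(), gid()
        labels = {"embedded": ("EIS", "EOS"), "overlapping": ("OIS", "OOS")}[arrangement]
        genes = [
            ("spanin_inner", 0, i_nt_len, "+", ip),
            ("spanin_outer", q, q + o_nt_len, "+", op),
        ]
        truth = [
            TruthRow(genome_id, i_id, 0, i_nt_len, "+", "spanin", labels[0], "pass", o_id),
            TruthRow(genome_id, o_id, q, q + o_nt_len, "+", "spanin", labels[1], "pass", i_id),
        ]
        return _Locus(locus_nt, genes, truth)
    raise ValueError(f"unknown spanin arrangement {arrangement!r}")


def _single_gene_locus(
    gene: PlantedGene, genome_id: str, gid: callable, vocab: MotifVocabulary,
    rng: np.random.Generator,
) -> _Locus:
    if gene.kind == "endolysin":
        protein, subclass, verdict = _endolysin_protein(gene, vocab, rng)
        role = "endolysin"
    elif gene.kind == "holin":
        protein, subclass, verdict = _holin_protein(gene, rng)
        role = "holin"
    elif gene.kind == "usp":
        protein, subclass, verdict = _usp_protein(rng, gene.reject)
        role = "usp"
    elif gene.kind in ("pE", "Pei", "PVAP"):
        protein = _accessory_protein(gene, vocab, rng)
        subclass, verdict = None, "pass"
        role = gene.kind
    elif gene.kind == "background":
        protein = "M" + _rand_aa(rng, int(rng.integers(50, 120)))
        subclass, verdict, role = None, None, "background"
    else:
        raise ValueError(f"unknown planted gene kind {gene.kind!r}")
    nt = _gene_nt(protein, rng)
    lytic_type = None if gene.kind == "background" else (
        "spanin" if gene.kind == "usp" else gene.kind
    )
    gene_id = gid()
    truth = [TruthRow(genome_id, gene_id, 0, len(nt), "+", lytic_type, subclass, verdict)]
    return _Locus(nt, [(role, 0, len(nt), "+", protein)], truth)


def _reflect_locus(locus: _Locus) -> _Locus:
    """Place a locus on the minus strand: reverse-complement the chunk and
    mirror every interval."""
    n = len(locus.nt)
    nt = _revcomp(locus.nt)
    genes = [
        (role, n - e, n - s, "-" if strand == "+" else "+", prot)
        for role, s, e, strand, prot in locus.genes
    ]
    truth = [
        TruthRow(r.genome_id, r.gene_id, n - r.end, n - r.start,
                 "-" if r.strand == "+" else "+", r.lytic_type, r.subclass,
                 r.verdict, r.partner_id)
        for r in locus.truth
    ]
    return _Locus(nt, genes, truth)


def generate_dataset(spec: PlantSpec, vocab: MotifVocabulary | None = None) -> SyntheticDataset:
    """Generate viral genomes + proteins + gene calls + truth table.

    Deterministic: identical spec + seed give byte-identical output.
    """
    vocab = vocab or default_vocabulary()
    rng = np.random.default_rng(spec.seed)
    genomes: list[SeqRecord] = []
    gene_calls: list[GeneCall] = []
    annotations: dict[str, str] = {}
    truth: list[TruthRow] = []

    for g_idx, plan in enumerate(spec.plans):
        genome_id = f"vg{g_idx:03d}"
        counter = iter(range(10_000))

        def gid() -> str:
            return f"{genome_id}_g{next(counter):03d}"

        loci: list[_Locus] = []
        for gene in plan.genes:
            if gene.kind == "spanin_pair":
                locus = _spanin_pair_locus(gene, genome_id, gid, rng)
            else:
                locus = _single_gene_locus(gene, genome_id, gid, vocab, rng)
            # multi-gene loci keep their internal geometry on either strand
            if rng.random() < 0.4:
                locus = _reflect_locus(locus)
            loci.append(locus)
        for _ in range(plan.n_background):
            locus = _single_gene_locus(PlantedGene("background"), genome_id, gid, vocab, rng)
            if rng.random() < 0.5:
                locus = _reflect_locus(locus)
            loci.append(locus)

        length = int(rng.integers(spec.genome_length[0], spec.genome_length[1] + 1))
        total_gene_nt = sum(len(l.nt) for l in loci)
        min_gap = 60
        needed = total_gene_nt + min_gap * (len(loci) + 1)
        if needed > length:
            raise ValueError(
                f"genome {genome_id}: length {length} nt cannot host "
                f"{len(loci)} loci needing {needed} nt"
            )
        spare = length - total_gene_nt
        cuts = np.sort(rng.choice(spare - (len(loci) + 1) * min_gap + 1, size=len(loci), replace=False)) \
            if spare - (len(loci) + 1) * min_gap + 1 > len(loci) else np.arange(len(loci))
        gaps = np.diff(np.concatenate([[0], cuts])) + min_gap
        parts = []
        pos = 0
        for locus, gap in zip(loci, gaps):
            parts.append(_rand_nt(rng, int(gap)))
            pos += int(gap)
            for (role, s, e, strand, protein), row in zip(locus.genes, locus.truth):
                call = GeneCall(
                    genome_id=genome_id,
                    gene_id=row.gene_id,
                    start=pos + row.start,
                    end=pos + row.end,
                    strand=row.strand,
                    codon_table=11,
                    protein=protein,
                )
                gene_calls.append(call)
                annotations[row.gene_id] = _ANNOTATIONS[role]
                truth.append(
                    TruthRow(genome_id, row.gene_id, pos + row.start, pos + row.end,
                             row.strand, row.lytic_type, row.subclass, row.verdict,
                             row.partner_id)
                )
            parts.append(locus.nt)
            pos += len(locus.nt)
        parts.append(_rand_nt(rng, length - pos))
        genome_nt = "".join(parts)
        genomes.append(SeqRecord(id=genome_id, residues=genome_nt, alphabet="nt", source="viral"))

    ds = SyntheticDataset(genomes, gene_calls, annotations, truth, vocab)
    _check_closure(ds)
    return ds


def _check_closure(ds: SyntheticDataset) -> None:
    """Every truth row resolves to an emitted gene whose in-genome sequence
    translates to the recorded protein."""
    calls = {c.gene_id: c for c in ds.gene_calls}
    genomes = {g.id: g.residues for g in ds.genomes}
    for row in ds.truth:
        call = calls[row.gene_id]
        nt = genomes[row.genome_id][row.start : row.end]
        if row.strand == "-":
            nt = _revcomp(nt)
        aa = _translate11(nt)
        if aa[-1] != "*" or ("M" + aa[1:-1]) != call.protein:
            raise AssertionError(f"truth closure violated for {row.gene_id}")


# ---------------------------------------------------------------------------
# Default study-scale plant spec


def default_plant_spec(n_genomes: int = 60, seed: int = 0) -> PlantSpec:
    """The standard desk-scale study conditions: >= 200 planted lytic genes
    over ``n_genomes`` genomes covering every endolysin subclass, holin TMR
    class, spanin architecture, the accessory types, and every designed
    QC-reject case."""
    e = PlantedGene
    endolysin_cycle = [
        e("endolysin", families=("Ami2_like",)),
        e("endolysin", families=("GH24_like",)),
        e("endolysin", families=("M23_like",)),
        e("endolysin", families=("SLT_like",)),
        e("endolysin", families=("GH73_like",)),
        e("endolysin", families=("Ami3_like", "M23_like")),  # m-EAD
        e("endolysin", families=("LysM_CBD",)),  # s-CBD
        e("endolysin", families=("EAD_X",)),  # unclassified
        e("endolysin", families=("Ami2_like",), reject="TMR"),
        e("endolysin", families=("VAL_gp5",)),  # reject:VAL
        e("endolysin", reject="no-domain"),
    ]
    holin_cycle = [
        e("holin", tmr_count=1),
        e("holin", tmr_count=2),
        e("holin", tmr_count=3),
        e("holin", tmr_count=4),
        e("holin", tmr_count=5),  # TMRs-4+
        e("holin", reject="no-TMR"),
    ]
    spanin_cycle = [
        e("spanin_pair", arrangement="separated"),
        e("spanin_pair", arrangement="embedded"),
        e("spanin_pair", arrangement="overlapping"),
        e("usp"),
        e("spanin_pair", arrangement="separated", reject="no-lipobox"),
        e("spanin_pair", arrangement="separated", reject="no-TMR"),
        e("usp", reject="no-TMR"),
    ]
    accessory_cycle = [e("pE"), e("Pei"), e("PVAP")]
    plans = []
    for i in range(n_genomes):
        genes = [
            endolysin_cycle[i % len(endolysin_cycle)],
            holin_cycle[i % len(holin_cycle)],
            spanin_cycle[i % len(spanin_cycle)],
        ]
        if i % 4 == 0:
            genes.append(accessory_cycle[(i // 4) % len(accessory_cycle)])
        plans.append(GenomePlan(genes=list(genes), n_background=3))
    return PlantSpec(plans=plans, seed=seed)


# ---------------------------------------------------------------------------
# CRISPR planting


def plant_crispr_link(
    host_genome: SeqRecord,
    viral_genome: SeqRecord,
    n_spacers: int = 4,
    repeat_len: int = 28,
    spacer_len: int = 32,
    mismatches: int = 0,
    seed: int = 0,
) -> tuple[SeqRecord, dict[str, str], list[dict]]:
    """Insert a CRISPR array whose spacers copy viral protospacers.

    Returns (modified host, spacer sequences keyed by id, truth links with
    viral position/strand/mismatch count).  Flanking nucleotides are
    re-drawn until no array boundary can be extended unanimously, so the
    planted repeat boundaries are exactly recoverable.
    """
    if mismatches > spacer_len:
        raise ValueError("more mismatches than spacer positions")
    rng = np.random.default_rng(seed)
    viral = viral_genome.residues.upper()
    if len(viral) < n_spacers * (spacer_len + 10):
        raise ValueError("viral genome too short to donate protospacers")
    for attempt in range(200):
        repeat = _rand_nt(rng, repeat_len)
        starts = rng.choice(len(viral) - spacer_len, size=n_spacers, replace=False)
        starts = np.sort(starts)
        if np.any(np.diff(starts) < spacer_len):
            continue
        spacers, links = {}, []
        for k, s in enumerate(starts):
            strand = "+" if rng.random() < 0.5 else "-"
            proto = viral[s : s + spacer_len]
            spacer = proto if strand == "+" else _revcomp(proto)
            if mismatches:
                spacer = mutate_sequence(spacer, mismatches / spacer_len, int(rng.integers(2**31)))
            sid = f"{host_genome.id}_sp{k}"
            spacers[sid] = spacer
            links.append(
                {"spacer_id": sid, "virus_id": viral_genome.id, "position": int(s),
                 "strand": strand, "mismatches": mismatches}
            )
        array = repeat + "".join(spacers[f"{host_genome.id}_sp{k}"] + repeat for k in range(n_spacers))
        # unanimity guard: flanks of the repeat instances must disagree
        left_flanks = {array[i - 1] for i in range(repeat_len + spacer_len, len(array), repeat_len + spacer_len)}
        right_flanks = {array[i + repeat_len] for i in range(0, len(array) - repeat_len - 1, repeat_len + spacer_len)}
        insert_at = int(rng.integers(100, len(host_genome.residues) - 100))
        host_left = host_genome.residues[insert_at - 1]
        host_right = host_genome.residues[insert_at]
        if len(left_flanks | {host_left}) < 2 or len(right_flanks | {host_right}) < 2:
            continue
        new_host = host_genome.residues[:insert_at] + array + host_genome.residues[insert_at:]
        modified = SeqRecord(id=host_genome.id, residues=new_host, alphabet="nt",
                             source=host_genome.source, taxonomy=host_genome.taxonomy)
        return modified, spacers, links
    raise RuntimeError("could not plant a boundary-safe CRISPR array")


# ---------------------------------------------------------------------------
# Tree pairs and transfer scenarios


def _random_tree(labels: list[str], rng: np.random.Generator) -> TreeNode:
    """Random bifurcating tree with uniform(0.2, 1.2) branch lengths."""
    nodes = [f"{lab}:{rng.uniform(0.2, 1.2):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        if len(nodes) == 0:
            nodes.append(f"({a},{b});")
        else:
            nodes.append(f"({a},{b}):{rng.uniform(0.2, 1.2):.6f}")
    return TreeNode.read(io.StringIO(nodes[0]))


def generate_tree_pair(
    n_leaves: int, incongruence: float, seed: int
) -> tuple[TreeNode, TreeNode, dict[str, str]]:
    """A random tree and a copy with round(incongruence * n) leaf swaps,
    plus the identity leaf association."""
    if n_leaves < 4:
        raise ValueError("need >= 4 leaves")
    if not (0.0 <= incongruence <= 1.0):
        raise ValueError("incongruence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = [f"T{i:03d}" for i in range(n_leaves)]
    tree_a = _random_tree(labels, rng)
    tree_b = tree_a.copy()
    n_swaps = round(incongruence * n_leaves)
    tips = list(tree_b.tips())
    for _ in range(n_swaps):
        i, j = rng.choice(len(tips), size=2, replace=False)
        tips[int(i)].name, tips[int(j)].name = tips[int(j)].name, tips[int(i)].name
    association = {lab: lab for lab in labels}
    return tree_a, tree_b, association


def simulate_hgt_cluster(
    n_donor: int = 4,
    n_recipient: int = 3,
    donor_step: float = 0.12,
    transfer_divergence: float = 0.02,
    radiation_divergence: float = 0.006,
    length: int = 150,
    seed: int = 0,
) -> tuple[list[SeqRecord], str]:
    """A clean transfer scenario: a diversified bacterial donor clade and a
    tight viral recipient clade radiating from a sequence transferred off
    the last donor branch (overall divergence from the donor <= ~5%).

    Returns (aligned protein records with source tags, donor source tag).
    """
    rng = np.random.default_rng(seed)
    ancestor = _rand_aa(rng, length, AA20)
    seqs = []
    current = ancestor
    for i in range(n_donor):
        current = mutate_sequence(current, donor_step, int(rng.integers(2**31)))
        seqs.append(SeqRecord(id=f"B{i}", residues=current, alphabet="aa", source="bacterial"))
    transferred = mutate_sequence(current, transfer_divergence, int(rng.integers(2**31)))
    for j in range(n_recipient):
        mutant = mutate_sequence(transferred, radiation_divergence, int(rng.integers(2**31)))
        seqs.append(SeqRecord(id=f"V{j}", residues=mutant, alphabet="aa", source="viral"))
    return seqs, "bacterial"
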