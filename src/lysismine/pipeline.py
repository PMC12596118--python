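"""End-to-end desk-scale pipeline: discovery routes, pooling, QC
classification, and evaluation against a planted truth table.

Discovery runs the published four-route scheme at desk scale: (1) profile
search of the annotated proteins, (2) keyword screening of annotations,
(3) keyword screening of an alternative annotation set when one is
supplied, (4) ORF re-prediction followed by the same profile search.
Candidates are pooled by genomic location, ORF-variant duplicates (same
stop codon, longer upstream start) are resolved in favour of annotated
coordinates, and each candidate is classified by the QC rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lysclass import (
    DomainHit,
    LypRecord,
    SpaninComplex,
    SpaninComponent,
    classify_endolysin,
    classify_holin,
    classify_spanin,
    predict_tmrs,
)
from .orfs import find_orfs
from .profiles import HitRecord, ProfileModel, build_profile, calibrate_profile, profile_search
from .screen import Candidate, keyword_type, merge_pipelines
from .synth import SCAFFOLD_AA, MotifVocabulary, SyntheticDataset, mutate_sequence

ACCESSORY_TYPES = ("pE", "Pei", "PVAP")


def build_family_profiles(
    vocab: MotifVocabulary,
    seed: int = 0,
    n_train: int = 8,
    train_divergence: float = 0.08,
    n_decoys: int = 600,
) -> dict[str, ProfileModel]:
    """One calibrated profile per vocabulary family.

    Training alignments are divergence-controlled copies of the family
    consensus; calibration decoys are random polar-composition proteins
    matching the background gene composition.
    """
    rng = np.random.default_rng(seed)
    decoys = [
        "".join(rng.choice(list(SCAFFOLD_AA), size=int(rng.integers(60, 250))))
        for _ in range(n_decoys)
    ]
    profiles = {}
    for name in sorted(vocab.families):
        fam = vocab.families[name]
        msa = [
            mutate_sequence(fam.motif, train_divergence, int(rng.integers(2**31)))
            for _ in range(n_train)
        ]
        profile = build_profile(msa, profile_id=name)
        profiles[name] = calibrate_profile(profile, decoys)
    return profiles


def screen_proteins(
    profiles: dict[str, ProfileModel],
    targets: dict[str, str],
    evalue_threshold: float = 1e-10,
) -> dict[str, list[HitRecord]]:
    """All-profile search; hits grouped by target id."""
    by_target: dict[str, list[HitRecord]] = {}
    for name in sorted(profiles):
        for hit in profile_search(profiles[name], targets, evalue_threshold):
            by_target.setdefault(hit.target_id, []).append(hit)
    return by_target


def hits_to_domains(hits: list[HitRecord], vocab: MotifVocabulary) -> list[DomainHit]:
    return [
        DomainHit(
            family=h.profile_id,
            category=vocab.families[h.profile_id].category,
            start=h.start,
            end=h.end,
            score=h.score,
        )
        for h in hits
    ]


# ---------------------------------------------------------------------------
# Discovery routes on a synthetic dataset


def discover_candidates(
    ds: SyntheticDataset,
    profiles: dict[str, ProfileModel],
    evalue_threshold: float = 1e-10,
    alt_annotations: dict[str, str] | None = None,
) -> tuple[list[Candidate], dict[str, list[HitRecord]]]:
    """Run the discovery routes and pool candidates.

    Returns (resolved candidates, profile hits keyed by candidate protein id).
    """
    calls = {c.gene_id: c for c in ds.gene_calls}
    annotated_hits = screen_proteins(profiles, ds.proteins, evalue_threshold)

    def call_candidate(gene_id: str, lytic_type: str | None) -> Candidate:
        c = calls[gene_id]
        return Candidate(
            genome_id=c.genome_id, start=c.start, end=c.end, strand=c.strand,
            protein=c.protein, protein_id=gene_id, lytic_type=lytic_type,
        )

    routes: dict[int, list[Candidate]] = {1: [], 2: [], 3: [], 4: []}
    vocab = ds.vocabulary
    for gene_id in sorted(annotated_hits):
        fams = sorted({h.profile_id for h in annotated_hits[gene_id]})
        lytic_type = vocab.families[fams[0]].lytic_type
        routes[1].append(call_candidate(gene_id, lytic_type))
    for gene_id in sorted(ds.annotations):
        ktype = keyword_type(ds.annotations[gene_id])
        if ktype is not None:
            routes[2].append(call_candidate(gene_id, ktype))
    if alt_annotations:
        for gene_id in sorted(alt_annotations):
            ktype = keyword_type(alt_annotations[gene_id])
            if ktype is not None and gene_id in calls:
                routes[3].append(call_candidate(gene_id, ktype))

    orf_proteins: dict[str, str] = {}
    orf_calls = {}
    for genome in ds.genomes:
        for call in find_orfs(genome, min_aa_len=30, codon_tables=(11,)):
            if len(call.protein) <= 500:
                orf_proteins[call.gene_id] = call.protein
                orf_calls[call.gene_id] = call
    orf_hits = screen_proteins(profiles, orf_proteins, evalue_threshold)
    for orf_id in sorted(orf_hits):
        c = orf_calls[orf_id]
        fams = sorted({h.profile_id for h in orf_hits[orf_id]})
        routes[4].append(
            Candidate(
                genome_id=c.genome_id, start=c.start, end=c.end, strand=c.strand,
                protein=c.protein, protein_id=orf_id,
                lytic_type=vocab.families[fams[0]].lytic_type,
            )
        )

    pooled = merge_pipelines(routes)
    resolved = resolve_orf_variants(pooled)
    hits_by_candidate: dict[str, list[HitRecord]] = {}
    for cand in resolved:
        hits = annotated_hits.get(cand.protein_id) or orf_hits.get(cand.protein_id) or []
        hits_by_candidate[cand.protein_id] = hits
    return resolved, hits_by_candidate


def resolve_orf_variants(candidates: list[Candidate]) -> list[Candidate]:
    """Collapse ORF-variant duplicates sharing a stop codon.

    Re-predicted ORFs may extend an annotated gene upstream to an earlier
    in-frame start; candidates sharing (genome, strand, stop anchor) are one
    gene.  The annotated version (found by routes 1-3) wins; provenance is
    unioned.
    """
    groups: dict[tuple, list[Candidate]] = {}
    for c in candidates:
        anchor = c.end if c.strand == "+" else c.start
        groups.setdefault((c.genome_id, c.strand, anchor), []).append(c)
    out = []
    for key in sorted(groups):
        group = groups[key]
        annotated = [c for c in group if c.routes & {1, 2, 3}]
        keep = annotated[0] if annotated else max(group, key=lambda c: len(c.protein))
        for c in group:
            if c is not keep:
                keep.routes |= c.routes
        out.append(keep)
    return out


# ---------------------------------------------------------------------------
# Classification


def classify_candidates(
    candidates: list[Candidate],
    hits_by_candidate: dict[str, list[HitRecord]],
    vocab: MotifVocabulary,
    pair_max_gap: int = 300,
) -> list[LypRecord]:
    """Apply the QC/classification rules to pooled candidates."""
    records: list[LypRecord] = []
    spanins: dict[str, list[Candidate]] = {}
    for cand in candidates:
        if cand.lytic_type == "spanin":
            spanins.setdefault(cand.genome_id, []).append(cand)
            continue
        prov = tuple(sorted(cand.routes))
        domains = hits_to_domains(hits_by_candidate.get(cand.protein_id, []), vocab)
        tmrs = predict_tmrs(cand.protein)
        if cand.lytic_type == "endolysin":
            records.append(classify_endolysin(cand.protein_id, domains, tmrs, prov))
        elif cand.lytic_type == "holin":
            records.append(classify_holin(cand.protein_id, tmrs, prov))
        elif cand.lytic_type in ACCESSORY_TYPES:
            ok = any(
                vocab.families[d.family].lytic_type == cand.lytic_type for d in domains
            )
            verdict = "pass" if ok else "reject:no-domain"
            records.append(LypRecord(cand.protein_id, cand.lytic_type, None, verdict, prov))
        # candidates without a type assignment are dropped silently

    for genome_id in sorted(spanins):
        group = sorted(spanins[genome_id], key=lambda c: (c.start, c.end))
        i = 0
        while i < len(group):
            a = group[i]
            paired = False
            if i + 1 < len(group):
                b = group[i + 1]
                if b.start < a.end or b.start - a.end <= pair_max_gap:
                    complex_ = SpaninComplex(
                        [
                            SpaninComponent(a.protein_id, a.start, a.end, a.strand, a.protein),
                            SpaninComponent(b.protein_id, b.start, b.end, b.strand, b.protein),
                        ]
                    )
                    prov = tuple(sorted(a.routes | b.routes))
                    records.extend(classify_spanin(complex_, prov))
                    i += 2
                    paired = True
            if not paired:
                complex_ = SpaninComplex(
                    [SpaninComponent(a.protein_id, a.start, a.end, a.strand, a.protein)]
                )
                records.extend(classify_spanin(complex_, tuple(sorted(a.routes))))
                i += 1
    records.sort(key=lambda r: r.protein_id)
    return records


def run_classification(
    ds: SyntheticDataset,
    profiles: dict[str, ProfileModel] | None = None,
    evalue_threshold: float = 1e-10,
    seed: int = 0,
) -> list[LypRecord]:
    """Full discovery + classification on a synthetic dataset."""
    if profiles is None:
        profiles = build_family_profiles(ds.vocabulary, seed=seed)
    candidates, hits = discover_candidates(ds, profiles, evalue_threshold)
    return classify_candidates(candidates, hits, ds.vocabulary)


# ---------------------------------------------------------------------------
# Truth comparison


@dataclass
class TruthComparison:
    n_truth: int
    n_correct: int
    mismatches: list[str]
    false_positives: list[str]

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_truth if self.n_truth else 1.0


def compare_to_truth(records: list[LypRecord], ds: SyntheticDataset) -> TruthComparison:
    """Per planted lytic gene: type, QC verdict and (for passing genes)
    subclass must all match the truth table."""
    by_id = {r.protein_id: r for r in records}
    mismatches = []
    truth_rows = ds.truth_lytic()
    n_correct = 0
    for row in truth_rows:
        rec = by_id.get(row.gene_id)
        if rec is None:
            mismatches.append(f"{row.gene_id}: not recovered")
            continue
        if rec.lytic_type != row.lytic_type:
            mismatches.append(f"{row.gene_id}: type {rec.lytic_type} != {row.lytic_type}")
        elif rec.verdict != row.verdict:
            mismatches.append(f"{row.gene_id}: verdict {rec.verdict} != {row.verdict}")
        elif row.verdict == "pass" and rec.subclass != row.subclass:
            mismatches.append(f"{row.gene_id}: subclass {rec.subclass} != {row.subclass}")
        else:
            n_correct += 1
    lytic_ids = {row.gene_id for row in truth_rows}
    false_positives = [r.protein_id for r in records if r.passed and r.protein_id not in lytic_ids]
    return TruthComparison(
        n_truth=len(truth_rows),
        n_correct=n_correct,
        mismatches=mismatches,
        false_positives=false_positives,
    )


def records_to_tsv(records: list[LypRecord]) -> str:
    lines = ["protein_id\tlytic_type\tsubclass\tverdict\tprovenance"]
    for r in records:
        prov = ",".join(str(x) for x in r.provenance)
        lines.append(f"{r.protein_id}\t{r.lytic_type}\t{r.subclass or '-'}\t{r.verdict}\t{prov}")
    return "\n".join(lines) + "\n"
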