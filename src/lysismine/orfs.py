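"""Minimal ORF caller over both strands and arbitrary codon tables.

Calls every maximal start-to-stop ORF (starts ATG/GTG/TTG, maximal = the
first start after the previous in-frame stop) whose translation reaches the
requested length, under each requested NCBI codon table.  The initiator
codon is always rendered as Met, as gene callers do.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .records import GeneCall, SeqRecord

START_CODONS = ("ATG", "GTG", "TTG")


def _scan_strand(
    seq: str,
    genome_len: int,
    strand: str,
    table: int,
    min_aa_len: int,
    genome_id: str,
) -> list[GeneCall]:
    stops = set(CodonTable.unambiguous_dna_by_id[table].stop_codons)
    calls = []
    n = len(seq)
    for frame in range(3):
        start_pos: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start_pos is None and codon in START_CODONS:
                start_pos = i
            if codon in stops:
                if start_pos is not None:
                    aa_len = (i - start_pos) // 3
                    if aa_len >= min_aa_len:
                        calls.append(
                            _make_call(seq, start_pos, i + 3, genome_len, strand, table, genome_id)
                        )
                start_pos = None
    return calls


def _make_call(
    seq: str, s: int, e: int, genome_len: int, strand: str, table: int, genome_id: str
) -> GeneCall:
    nt = seq[s:e]
    protein = str(Seq(nt).translate(table=table))
    assert protein.endswith("*")
    protein = "M" + protein[1:-1]
    if strand == "+":
        start, end = s, e
    else:
        start, end = genome_len - e, genome_len - s
    return GeneCall(
        genome_id=genome_id,
        gene_id=f"{genome_id}|{start}-{end}|{strand}|t{table}",
        start=start,
        end=end,
        strand=strand,
        codon_table=table,
        protein=protein,
    )


def find_orfs(
    genome: SeqRecord,
    min_aa_len: int = 30,
    codon_tables: tuple[int, ...] = (11,),
) -> list[GeneCall]:
    """All maximal ORFs on both strands under each requested codon table,
    deduplicated by (coordinates, strand, table)."""
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    if genome.alphabet != "nt":
        raise ValueError("find_orfs requires a nucleotide record")
    fwd = genome.residues.upper()
    rev = str(Seq(fwd).reverse_complement())
    seen: set[tuple[int, int, str, int]] = set()
    out: list[GeneCall] = []
    for table in codon_tables:
        for strand, seq in (("+", fwd), ("-", rev)):
            for call in _scan_strand(seq, len(fwd), strand, table, min_aa_len, genome.id):
                key = (call.start, call.end, call.strand, call.codon_table)
                if key not in seen:
                    seen.add(key)
                    out.append(call)
    out.sort(key=lambda c: (c.start, c.end, c.strand, c.codon_table))
    return out
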