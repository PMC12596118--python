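"""Sequence records, gene calls, and plain-text I/O (FASTA, GFF3, TSV).

The in-memory containers are deliberately small: a :class:`SeqRecord` is an
id, an alphabet, a residue string and an optional source tag / taxonomy path;
a :class:`GeneCall` is a genomic interval (0-based half-open, nucleotides)
with strand, codon table and the translated protein.  File formats go through
Biopython so coordinates only have to be converted once, at the boundary
(GFF3 is 1-based inclusive).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

NT_ALPHABET = set("ACGTRYSWKMBDHVN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*", "-", "."}  # gaps for aligned sets

SOURCE_TAGS = ("viral", "bacterial", "archaeal", "unknown")


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence with a declared alphabet and an origin tag."""

    id: str
    residues: str
    alphabet: str = "aa"  # "nt" or "aa"
    source: str = "unknown"
    taxonomy: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} not in {self.alphabet} alphabet"
            )
        if self.source not in SOURCE_TAGS:
            raise ValueError(f"unknown source tag {self.source!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SeqRecord":
        if self.alphabet != "nt":
            raise ValueError("reverse_complement only defined for nt records")
        return SeqRecord(
            id=self.id,
            residues=str(Seq(self.residues).reverse_complement()),
            alphabet="nt",
            source=self.source,
            taxonomy=self.taxonomy,
        )


@dataclass(frozen=True)
class GeneCall:
    """A called ORF on a genome; coordinates are 0-based half-open on the
    forward strand, length divisible by 3 including the stop codon."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    codon_table: int = 11
    protein: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: bad interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def nt_length(self) -> int:
        return self.end - self.start


def check_unique_ids(records: Sequence[SeqRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(records: Iterable[SeqRecord], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def read_fasta(path: str, alphabet: str = "nt", source: str = "unknown") -> list[SeqRecord]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        out.append(SeqRecord(id=rec.id, residues=str(rec.seq).upper(), alphabet=alphabet, source=source))
    check_unique_ids(out)
    return out


def fasta_bytes(records: Iterable[SeqRecord], width: int = 70) -> bytes:
    buf = io.StringIO()
    for r in records:
        buf.write(f">{r.id}\n")
        for i in range(0, len(r.residues), width):
            buf.write(r.residues[i : i + width] + "\n")
    return buf.getvalue().encode()


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk; 0-based half-open in memory)

def write_gff3(calls: Iterable[GeneCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in calls:
            attrs = f"ID={c.gene_id};transl_table={c.codon_table}"
            fh.write(
                "\t".join(
                    [
                        c.genome_id,
                        "lysismine",
                        "CDS",
                        str(c.start + 1),
                        str(c.end),
                        ".",
                        c.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str) -> list[GeneCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            calls.append(
                GeneCall(
                    genome_id=f[0],
                    gene_id=attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    codon_table=int(attrs.get("transl_table", 11)),
                )
            )
    return calls


def translate(nt: str, table: int = 11) -> str:
    """Translate a complete ORF (with stop) to its protein, stop stripped."""
    aa = str(Seq(nt).translate(table=table))
    return aa[:-1] if aa.endswith("*") else aa
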