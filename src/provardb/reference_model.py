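"""Reference genome and annotation layer.

Loads a genome FASTA and a GTF annotation into strand-aware transcript
models and provides the sequence-extraction and translation primitives the
database-construction stages build on.

Coordinate convention
---------------------
Everything internal is 0-based, half-open ``[start, end)``. GTF (1-based,
closed) and VCF (1-based) coordinates are converted at the parser boundary;
BED is already 0-based half-open. One convention everywhere removes the
classic off-by-one class of bugs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("provardb")

# IUPAC nucleotide one-letter codes; ambiguity codes collapse to N on read.
_IUPAC_NT = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = set("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP = "*"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript, strand-aware.

    ``intervals`` are the exons in genomic order (sorted by start,
    non-overlapping); ``cds_intervals`` is the coding subset, possibly empty
    for non-coding transcripts. Strand ``.`` marks an unstranded model,
    which downstream translation treats with six frames.
    """

    transcript_id: str
    gene_id: str
    intervals: List[GenomicInterval]
    cds_intervals: List[GenomicInterval] = field(default_factory=list)
    strand: str = "."

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.intervals[0].start, self.intervals[-1].end, self.strand
        )


@dataclass
class GeneticCode:
    """A 64-entry codon table; stops map to ``*``."""

    codon_table: Dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_table) != 64:
            raise ValueError("codon table must have exactly 64 entries")

    @classmethod
    def standard(cls, table_id: int = 1) -> "GeneticCode":
        """Build a complete codon→aa map from an NCBI table (default 1)."""
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for codon in ncbi.stop_codons:
            table[codon] = STOP
        if len(table) != 64:  # pragma: no cover - NCBI tables are complete
            raise ValueError(f"incomplete codon table {table_id}")
        return cls(table)


STANDARD_CODE = GeneticCode.standard(1)


# ---------------------------------------------------------------------------
# FASTA genome
# ---------------------------------------------------------------------------

def read_genome(path) -> Dict[str, str]:
    """Read a genome FASTA into a map of chromosome name → sequence.

    Headers are truncated at the first whitespace. Lowercase is uppercased,
    U becomes T, and IUPAC ambiguity codes collapse to N. A duplicate header
    or a non-IUPAC character is a hard error.
    """
    genome: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in genome:
            raise ValueError(f"duplicate FASTA header {name!r} in {path}")
        seq = str(record.seq).upper().replace("U", "T")
        cleaned = []
        for i, base in enumerate(seq):
            if base in "ACGTN":
                cleaned.append(base)
            elif base in _AMBIGUOUS:
                cleaned.append("N")
            else:
                raise ValueError(
                    f"non-IUPAC character {base!r} at position {i + 1} of {name}"
                )
        if not cleaned:
            raise ValueError(f"empty sequence for {name!r} in {path}")
        genome[name] = "".join(cleaned)
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path) -> List[TranscriptModel]:
    """Parse a GTF (Cufflinks dialect) into transcript models.

    Only ``exon`` and ``CDS`` features are consumed. GTF 1-based closed
    coordinates become internal 0-based half-open. Exons are sorted per
    transcript; an exon without a transcript_id, or overlapping exons within
    one transcript, are hard errors.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    cds: Dict[str, List[GenomicInterval]] = {}
    genes: Dict[str, str] = {}
    order: List[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}:{lineno}: {feature} without transcript_id")
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if tid not in exons:
                exons[tid] = []
                cds[tid] = []
                order.append(tid)
            genes.setdefault(tid, attr.get("gene_id", tid))
            (exons if feature == "exon" else cds)[tid].append(iv)

    models = []
    for tid in order:
        ex = sorted(exons[tid], key=lambda iv: iv.start)
        if not ex:
            # CDS-only transcript: treat CDS intervals as its exons too
            ex = sorted(cds[tid], key=lambda iv: iv.start)
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {tid!r}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        strand = ex[0].strand
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=genes[tid],
                intervals=ex,
                cds_intervals=sorted(cds[tid], key=lambda iv: iv.start),
                strand=strand,
            )
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcript models back to GTF (exon + CDS features).

    Inverse of :func:`read_gtf` on its own output; used by the fixture
    generator and for coordinate round-trip checks.
    """
    with open(path, "w") as fh:
        for tx in transcripts:
            for feature, ivs in (("exon", tx.intervals), ("CDS", tx.cds_intervals)):
                for iv in ivs:
                    attrs = (
                        f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        f"{iv.chrom}\tprovardb\t{feature}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{tx.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Sequence extraction and translation
# ---------------------------------------------------------------------------

def _extract(intervals: List[GenomicInterval], genome: Dict[str, str], strand: str) -> str:
    parts = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {len(chrom_seq)}"
            )
        parts.append(chrom_seq[iv.start : iv.end])
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq


def spliced_sequence(tx: TranscriptModel, genome: Dict[str, str]) -> str:
    """Spliced exonic sequence of ``tx``, 5'→3' on the coding strand."""
    return _extract(tx.intervals, genome, tx.strand)


def cds_sequence(tx: TranscriptModel, genome: Dict[str, str]) -> str:
    """Spliced CDS sequence of ``tx``, 5'→3' on the coding strand."""
    if not tx.cds_intervals:
        raise ValueError(f"transcript {tx.transcript_id!r} has no CDS")
    return _extract(tx.cds_intervals, genome, tx.strand)


def translate(
    seq: str, code: GeneticCode = STANDARD_CODE, to_first_stop: bool = False
) -> str:
    """Translate a DNA string codon by codon.

    A trailing partial codon is ignored. Codons containing N translate to X.
    With ``to_first_stop`` the product is truncated at the first stop codon;
    otherwise stops render as ``*``.
    """
    table = code.codon_table
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aa = table.get(codon)
        if aa is None:
            aa = "X"  # N-containing or otherwise ambiguous codon
        if aa == STOP and to_first_stop:
            break
        out.append(aa)
    return "".join(out)
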