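"""Splice-junction peptide candidates from TopHat-style BED12 junctions.

For each junction, up to ``flank_nt`` nucleotides on either side of the
intron are concatenated and translated — three frames when the strand is
known, six when it is not. Each frame's translation is cut at stop codons
and only fragments that straddle the junction (at least one nucleotide
encoded on each side) become database entries.

Junctions identical to annotated introns are not removed here: novelty is
decided downstream by mapping identified peptides against the reference
proteome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List

from .db_assembly import DatabaseEntry
from .reference_model import (
    STANDARD_CODE,
    GeneticCode,
    GenomicInterval,
    reverse_complement,
    translate,
)

logger = logging.getLogger("provardb")

DEFAULT_FLANK_NT = 66  # up to 22 aa per side, covers typical tryptic peptides


@dataclass
class JunctionRecord:
    """One exon–exon junction: two flanking blocks around an intron."""

    chrom: str
    left_block: GenomicInterval
    right_block: GenomicInterval
    strand: str
    name: str
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.left_block.end > self.right_block.start:
            raise ValueError(
                f"junction {self.name!r}: blocks overlap the intron "
                f"({self.left_block.end} > {self.right_block.start})"
            )


@dataclass
class JunctionPeptideEntry:
    """A junction-spanning translation fragment with its frame bookkeeping."""

    entry: DatabaseEntry
    junction_offset: int  # 0-based index of the last residue encoded left of the junction
    frame: int
    translated_strand: str


def read_junction_bed(path, min_reads: int = 0) -> List[JunctionRecord]:
    """Read a BED12 junction file (TopHat junctions.bed dialect).

    Each usable record has exactly two blocks; anything else is skipped with
    a warning. The score column is kept as the junction read count and
    records below ``min_reads`` are dropped.
    """
    records: List[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                logger.warning("%s:%d: not BED12; skipped", path, lineno)
                continue
            chrom = fields[0]
            chrom_start = int(fields[1])
            name = fields[3]
            try:
                read_count = int(float(fields[4]))
            except ValueError:
                read_count = 0
            strand = fields[5] if fields[5] in ("+", "-") else "."
            block_count = int(fields[9])
            if block_count != 2:
                logger.warning(
                    "%s:%d: junction %r has %d blocks, expected 2; skipped",
                    path, lineno, name, block_count,
                )
                continue
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            left = GenomicInterval(
                chrom, chrom_start + starts[0], chrom_start + starts[0] + sizes[0], strand
            )
            right = GenomicInterval(
                chrom, chrom_start + starts[1], chrom_start + starts[1] + sizes[1], strand
            )
            if read_count < min_reads:
                continue
            records.append(
                JunctionRecord(
                    chrom=chrom,
                    left_block=left,
                    right_block=right,
                    strand=strand,
                    name=name,
                    read_count=read_count,
                )
            )
    return records


def _spanning_fragments(
    seq: str,
    junction_idx: int,
    frames: List[int],
    strand_label: str,
    code: GeneticCode,
    min_protein_len: int,
    j: JunctionRecord,
) -> List[JunctionPeptideEntry]:
    """Translate ``seq`` in the given frame offsets and keep junction-spanning
    stop-free fragments."""
    out: List[JunctionPeptideEntry] = []
    for frame in frames:
        protein = translate(seq[frame:], code)
        # walk stop-delimited fragments, tracking codon coordinates
        start = 0
        for chunk in protein.split("*"):
            if chunk:
                nt_start = frame + 3 * start
                # residues whose codon starts left of the junction
                left_res = [
                    k for k in range(len(chunk))
                    if nt_start + 3 * k < junction_idx
                ]
                nt_end = nt_start + 3 * len(chunk)
                has_right_nt = nt_end > junction_idx
                if left_res and has_right_nt:
                    offset = max(left_res)
                    if offset < len(chunk) - 1 and len(chunk) >= min_protein_len:
                        acc = (
                            f"VAR|JUC|{j.name}|{j.chrom}:{j.left_block.end}-"
                            f"{j.right_block.start}|frame{frame}|strand{strand_label}"
                        )
                        out.append(
                            JunctionPeptideEntry(
                                entry=DatabaseEntry(
                                    accession=acc,
                                    sequence=chunk,
                                    category="JUC",
                                    provenance={
                                        "junction": j.name,
                                        "frame": str(frame),
                                        "strand": strand_label,
                                        "junction_offset": str(offset),
                                        "reads": str(j.read_count),
                                    },
                                ),
                                junction_offset=offset,
                                frame=frame,
                                translated_strand=strand_label,
                            )
                        )
            start += len(chunk) + 1
    return out


def junction_to_entries(
    j: JunctionRecord,
    genome: Dict[str, str],
    flank_nt: int = DEFAULT_FLANK_NT,
    code: GeneticCode = STANDARD_CODE,
    min_protein_len: int = 7,
) -> List[JunctionPeptideEntry]:
    """Candidate peptide entries for one junction.

    The flanks are clipped at the block boundaries. Stranded junctions are
    translated in three frames on their strand; unstranded in all six.
    """
    if j.chrom not in genome:
        raise KeyError(f"chromosome {j.chrom!r} not in genome")
    chrom_seq = genome[j.chrom]
    if j.right_block.end > len(chrom_seq):
        raise ValueError(f"junction {j.name!r} outside chromosome bounds")

    left_start = max(j.left_block.start, j.left_block.end - flank_nt)
    right_end = min(j.right_block.end, j.right_block.start + flank_nt)
    left_seq = chrom_seq[left_start : j.left_block.end]
    right_seq = chrom_seq[j.right_block.start : right_end]
    concat = left_seq + right_seq
    junction_idx = len(left_seq)  # first nt encoded right of the junction

    results: List[JunctionPeptideEntry] = []
    frames = [0, 1, 2]
    if j.strand in ("+", "."):
        results.extend(
            _spanning_fragments(concat, junction_idx, frames, "+", code,
                                min_protein_len, j)
        )
    if j.strand in ("-", "."):
        rc = reverse_complement(concat)
        rc_junction = len(concat) - junction_idx
        results.extend(
            _spanning_fragments(rc, rc_junction, frames, "-", code,
                                min_protein_len, j)
        )
    return results


def junction_entries(
    junctions: List[JunctionRecord],
    genome: Dict[str, str],
    flank_nt: int = DEFAULT_FLANK_NT,
    code: GeneticCode = STANDARD_CODE,
    min_protein_len: int = 7,
) -> List[DatabaseEntry]:
    """Flatten junction peptide entries for database assembly."""
    entries: List[DatabaseEntry] = []
    for j in junctions:
        for jp in junction_to_entries(j, genome, flank_nt, code, min_protein_len):
            entries.append(jp.entry)
    return entries
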