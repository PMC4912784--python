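"""Protein entries from novel and de-novo assembled transcripts.

Novel transcripts reconstructed on the genome (GTF) and de-novo assemblies
(FASTA, e.g. Trinity output) are translated either stop-to-stop in three
frames (strand known) or six frames (strand unknown), or reduced to the
longest open reading frame across all frames.

Frame numbering: 0–2 read the given sequence at offsets 0/1/2; 3–5 read the
reverse complement at the same offsets and only exist for unstranded input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from Bio import SeqIO
from intervaltree import IntervalTree

from .db_assembly import DatabaseEntry
from .reference_model import (
    STANDARD_CODE,
    GeneticCode,
    TranscriptModel,
    reverse_complement,
    spliced_sequence,
    translate,
)

logger = logging.getLogger("provardb")

MODES = ("three_frame", "six_frame", "longest_orf")


@dataclass
class TranslationPolicy:
    """How a transcript becomes protein entries."""

    mode: str = "six_frame"
    min_protein_len: int = 7
    orf_requires_start: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown translation mode {self.mode!r}")
        if self.min_protein_len < 1:
            raise ValueError("min_protein_len must be ≥ 1")


@dataclass
class OrfCall:
    """One open reading frame; nt_end includes the stop codon when present."""

    frame: int
    nt_start: int
    nt_end: int
    protein: str


def frames_of(seq: str, stranded: bool) -> List[Tuple[int, str]]:
    """Reading sequences for each frame, offset already applied.

    Frames 0–2 on ``seq``; when not stranded, frames 3–5 on its reverse
    complement.
    """
    frames = [(k, seq[k:]) for k in range(3)]
    if not stranded:
        rc = reverse_complement(seq)
        frames.extend((k + 3, rc[k:]) for k in range(3))
    return frames


def stop_to_stop_fragments(
    seq: str,
    policy: TranslationPolicy,
    transcript_id: str,
    code: GeneticCode = STANDARD_CODE,
    provenance: Optional[Dict[str, str]] = None,
) -> List[DatabaseEntry]:
    """All stop-free translation fragments ≥ the minimum protein length."""
    if policy.mode not in ("three_frame", "six_frame"):
        raise ValueError(f"mode {policy.mode!r} is not a frame-translation mode")
    stranded = policy.mode == "three_frame"
    entries: List[DatabaseEntry] = []
    for frame, reading in frames_of(seq, stranded):
        protein = translate(reading, code)
        frag_no = 0
        for chunk in protein.split("*"):
            if len(chunk) >= policy.min_protein_len:
                frag_no += 1
                prov = dict(provenance or {})
                prov.update({"transcript_id": transcript_id, "frame": str(frame)})
                entries.append(
                    DatabaseEntry(
                        accession=f"VAR|NTX|{transcript_id}|frame{frame}|frag{frag_no}",
                        sequence=chunk,
                        category="NTX",
                        provenance=prov,
                    )
                )
    return entries


def longest_orf(
    seq: str,
    policy: TranslationPolicy,
    stranded: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> Optional[OrfCall]:
    """The maximal-length ORF over all frames (3 if stranded, else 6).

    With ``orf_requires_start`` an ORF runs ATG→stop (or sequence end);
    otherwise it is any stop-to-stop open stretch. Ties break toward the
    lower frame index, then the smaller start position (positions are in
    the reading sequence of that frame's strand).
    """
    best: Optional[OrfCall] = None
    for frame, reading in frames_of(seq, stranded):
        offset = frame % 3
        protein = translate(reading, code)
        # scan stop-delimited stretches in codon space
        start_codon = 0
        for chunk in protein.split("*"):
            has_stop = start_codon + len(chunk) < len(protein)
            if policy.orf_requires_start:
                atg = chunk.find("M")
                if atg < 0:
                    start_codon += len(chunk) + 1
                    continue
                orf_protein = chunk[atg:]
                orf_start_codon = start_codon + atg
            else:
                orf_protein = chunk
                orf_start_codon = start_codon
            if orf_protein:
                nt_start = offset + 3 * orf_start_codon
                nt_end = offset + 3 * (start_codon + len(chunk) + (1 if has_stop else 0))
                call = OrfCall(frame, nt_start, nt_end, orf_protein)
                if best is None or len(call.protein) > len(best.protein):
                    best = call
            start_codon += len(chunk) + 1
    if best is None or len(best.protein) < policy.min_protein_len:
        return None
    return best


# ---------------------------------------------------------------------------
# Higher-level entry builders
# ---------------------------------------------------------------------------

def _gene_overlap_tree(annotation: List[TranscriptModel]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for tx in annotation:
        span = tx.span
        trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, tx.gene_id)
    return trees


def overlaps_annotated_gene(
    tx: TranscriptModel, trees: Dict[str, IntervalTree]
) -> bool:
    tree = trees.get(tx.chrom)
    if tree is None:
        return False
    span = tx.span
    return bool(tree.overlap(span.start, span.end))


def _entries_for_sequence(
    seq: str,
    transcript_id: str,
    stranded: bool,
    policy: TranslationPolicy,
    code: GeneticCode,
    provenance: Dict[str, str],
) -> List[DatabaseEntry]:
    if policy.mode == "longest_orf":
        call = longest_orf(seq, policy, stranded=stranded, code=code)
        if call is None:
            return []
        prov = dict(provenance)
        prov.update(
            {
                "transcript_id": transcript_id,
                "frame": str(call.frame),
                "orf_nt": f"{call.nt_start}-{call.nt_end}",
            }
        )
        return [
            DatabaseEntry(
                accession=f"VAR|NTX|{transcript_id}|frame{call.frame}|frag1",
                sequence=call.protein,
                category="NTX",
                provenance=prov,
            )
        ]
    mode = "three_frame" if stranded else "six_frame"
    frame_policy = TranslationPolicy(
        mode=mode,
        min_protein_len=policy.min_protein_len,
        orf_requires_start=policy.orf_requires_start,
    )
    return stop_to_stop_fragments(seq, frame_policy, transcript_id, code, provenance)


def novel_transcript_entries(
    novel: List[TranscriptModel],
    genome: Dict[str, str],
    annotation: List[TranscriptModel],
    policy: Optional[TranslationPolicy] = None,
    code: GeneticCode = STANDARD_CODE,
) -> List[DatabaseEntry]:
    """Entries for genome-anchored novel transcripts.

    Stranded transcripts get three-frame translation, unstranded six-frame
    (or the longest ORF when the policy says so). Overlap with any annotated
    gene locus is recorded in provenance for the later novel-gene
    classification; overlapping transcripts are still translated.
    """
    policy = policy or TranslationPolicy(mode="three_frame")
    trees = _gene_overlap_tree(annotation)
    entries: List[DatabaseEntry] = []
    for tx in novel:
        seq = spliced_sequence(tx, genome)
        stranded = tx.strand in ("+", "-") and policy.mode != "six_frame"
        overlap = overlaps_annotated_gene(tx, trees)
        entries.extend(
            _entries_for_sequence(
                seq,
                tx.transcript_id,
                stranded,
                policy,
                code,
                {"gene_overlap": "1" if overlap else "0", "source": "novel_gtf"},
            )
        )
    return entries


def denovo_transcript_entries(
    fasta_path,
    policy: Optional[TranslationPolicy] = None,
    code: GeneticCode = STANDARD_CODE,
) -> List[DatabaseEntry]:
    """Entries for de-novo assembled transcripts (strand unknown → six frames)."""
    policy = policy or TranslationPolicy(mode="six_frame")
    entries: List[DatabaseEntry] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        entries.extend(
            _entries_for_sequence(
                seq,
                record.id,
                stranded=False,
                policy=policy,
                code=code,
                provenance={"gene_overlap": "0", "source": "denovo_fasta"},
            )
        )
    return entries
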