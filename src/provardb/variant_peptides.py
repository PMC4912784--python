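"""Variant protein products from VCF SNVs and INDELs.

Each variant is projected onto the spliced CDS of every overlapping
transcript, classified at the protein level, and rendered as a full-length
variant protein entry: a single-residue substitution for a missense SNV, a
truncated product for a stop gain, and a re-translated product through the
new first stop for frameshift and in-frame INDELs.

Variants are applied one at a time; co-occurring variants are not
haplotype-phased. A variant spanning an exon–intron boundary has no defined
spliced product and is dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Set

import pysam

from .db_assembly import DatabaseEntry
from .reference_model import (
    STANDARD_CODE,
    GeneticCode,
    TranscriptModel,
    cds_sequence,
    reverse_complement,
    translate,
)

logger = logging.getLogger("provardb")

EFFECT_CLASSES = (
    "synonymous",
    "missense",
    "stop_gain",
    "stop_loss",
    "frameshift",
    "inframe_indel",
    "noncoding",
)

DEFAULT_KEEP_FILTERS = frozenset({"PASS", "."})


@dataclass(frozen=True)
class VariantRecord:
    """One SNV or small INDEL in VCF (1-based) coordinates."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_id: str

    def __post_init__(self) -> None:
        if not self.ref_allele:
            raise ValueError(f"variant {self.variant_id!r}: empty REF allele")
        if self.pos < 1:
            raise ValueError(f"variant {self.variant_id!r}: position must be ≥ 1")

    @property
    def var_type(self) -> str:
        if len(self.ref_allele) == len(self.alt_allele) == 1:
            return "SNV"
        return "INS" if len(self.alt_allele) > len(self.ref_allele) else "DEL"


@dataclass
class VariantEffect:
    """Protein-level consequence of one variant on one transcript."""

    transcript_id: str
    cds_position: int  # 0-based nt offset within the spliced CDS
    ref_aa: str
    alt_aa: str
    effect_class: str
    variant: VariantRecord

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

def read_vcf(path, keep_filters: frozenset = DEFAULT_KEEP_FILTERS) -> List[VariantRecord]:
    """Read SNVs and INDELs from a VCF v4.x file.

    Multi-allelic records split into one record per ALT. Symbolic ALTs
    (``<DEL>`` etc.) and breakend notation are skipped with a warning.
    FILTER policy: keep records whose filter field is in ``keep_filters``
    (default PASS and '.'); pass ``None`` to keep everything.
    """
    records: List[VariantRecord] = []
    counter = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            filters = set(rec.filter.keys()) or {"."}
            if keep_filters is not None and not filters & set(keep_filters):
                continue
            for alt in rec.alts or ():
                counter += 1
                if alt.startswith("<") or any(c in alt for c in "[]."):
                    logger.warning(
                        "skipping symbolic ALT %r at %s:%d", alt, rec.chrom, rec.pos
                    )
                    continue
                vid = rec.id or f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}"
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt.upper(),
                        variant_id=vid,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Projection onto the spliced CDS
# ---------------------------------------------------------------------------

def _cds_genomic_positions(tx: TranscriptModel) -> List[int]:
    """Genomic positions of the spliced CDS in 5'→3' (coding) order."""
    positions: List[int] = []
    for iv in tx.cds_intervals:
        positions.extend(range(iv.start, iv.end))
    if tx.strand == "-":
        positions.reverse()
    return positions


def project_variant(
    v: VariantRecord,
    tx: TranscriptModel,
    genome: Dict[str, str],
    code: GeneticCode = STANDARD_CODE,
) -> Optional[VariantEffect]:
    """Project a variant onto one transcript's spliced CDS.

    Returns None when the variant does not touch the spliced CDS. A variant
    that only partially overlaps the CDS (spans a CDS/intron boundary) is
    classified ``noncoding`` and logged. Minus-strand alleles are
    reverse-complemented into coding-strand space.
    """
    if not tx.cds_intervals:
        raise ValueError(f"transcript {tx.transcript_id!r} has no CDS")
    if v.chrom != tx.chrom:
        return None

    ref_span = set(range(v.pos - 1, v.pos - 1 + len(v.ref_allele)))
    gpos = _cds_genomic_positions(tx)
    index_of = {g: i for i, g in enumerate(gpos)}
    hit = ref_span & index_of.keys()
    if not hit:
        return None
    if len(hit) != len(ref_span):
        logger.warning(
            "variant %s spans a CDS boundary on %s; dropped as noncoding",
            v.variant_id,
            tx.transcript_id,
        )
        return VariantEffect(tx.transcript_id, min(index_of[g] for g in hit), "", "",
                             "noncoding", v)

    cds_indices = sorted(index_of[g] for g in ref_span)
    if cds_indices != list(range(cds_indices[0], cds_indices[-1] + 1)):
        # ref allele broken across an intron in CDS space
        logger.warning(
            "variant %s is discontiguous in CDS space on %s; dropped as noncoding",
            v.variant_id,
            tx.transcript_id,
        )
        return VariantEffect(tx.transcript_id, cds_indices[0], "", "", "noncoding", v)

    i = cds_indices[0]
    if tx.strand == "-":
        ref_cds = reverse_complement(v.ref_allele)
        alt_cds = reverse_complement(v.alt_allele)
    else:
        ref_cds = v.ref_allele
        alt_cds = v.alt_allele

    cds = cds_sequence(tx, genome)
    if cds[i : i + len(ref_cds)] != ref_cds:
        raise ValueError(
            f"variant {v.variant_id}: REF allele does not match the reference "
            f"CDS of {tx.transcript_id} at CDS offset {i}"
        )

    if v.var_type == "SNV":
        codon_start = i - i % 3
        ref_codon = cds[codon_start : codon_start + 3]
        alt_codon = (
            ref_codon[: i % 3] + alt_cds + ref_codon[i % 3 + 1 :]
        )
        if len(ref_codon) < 3:  # SNV in a trailing partial codon
            return VariantEffect(tx.transcript_id, i, "", "", "noncoding", v)
        ref_aa = translate(ref_codon, code)
        alt_aa = translate(alt_codon, code)
        if ref_aa == alt_aa:
            cls = "synonymous"
        elif alt_aa == "*":
            cls = "stop_gain"
        elif ref_aa == "*":
            cls = "stop_loss"
        else:
            cls = "missense"
        return VariantEffect(tx.transcript_id, i, ref_aa, alt_aa, cls, v)

    # INDEL
    shift = abs(len(alt_cds) - len(ref_cds))
    cls = "frameshift" if shift % 3 else "inframe_indel"
    return VariantEffect(tx.transcript_id, i, "", "", cls, v)


def mutated_cds(effect: VariantEffect, cds: str, strand: str) -> str:
    """Apply an effect's edit to the spliced CDS string, strand-aware."""
    v = effect.variant
    i = effect.cds_position
    if strand == "-":
        ref_cds = reverse_complement(v.ref_allele)
        alt_cds = reverse_complement(v.alt_allele)
    else:
        ref_cds = v.ref_allele
        alt_cds = v.alt_allele
    if cds[i : i + len(ref_cds)] != ref_cds:
        raise ValueError(
            f"variant {v.variant_id}: CDS/allele mismatch at offset {i}"
        )
    return cds[:i] + alt_cds + cds[i + len(ref_cds) :]


def build_variant_entries(
    effects: List[VariantEffect],
    tx: TranscriptModel,
    genome: Dict[str, str],
    code: GeneticCode = STANDARD_CODE,
    min_protein_len: int = 7,
) -> List[DatabaseEntry]:
    """Render variant effects on one transcript into database entries.

    Missense and stop-loss → full-length variant protein; stop-gain → the
    truncated product (kept when ≥ ``min_protein_len``); frameshift and
    in-frame INDELs → translation of the edited CDS through the new first
    stop. Synonymous and noncoding effects emit nothing.
    """
    entries: List[DatabaseEntry] = []
    cds = cds_sequence(tx, genome)
    ref_protein = translate(cds, code, to_first_stop=True)
    for eff in effects:
        if eff.transcript_id != tx.transcript_id:
            raise ValueError("effect does not belong to this transcript")
        if eff.effect_class in ("synonymous", "noncoding"):
            continue
        v = eff.variant
        if eff.effect_class in ("missense", "stop_gain", "stop_loss"):
            aa_pos = eff.cds_position // 3
            if eff.effect_class == "missense":
                if aa_pos >= len(ref_protein):
                    continue  # substitution lands past an early reference stop
                seq = ref_protein[:aa_pos] + eff.alt_aa + ref_protein[aa_pos + 1 :]
            else:
                seq = translate(mutated_cds(eff, cds, tx.strand), code, to_first_stop=True)
            header_tail = f"{eff.cds_position}:{eff.ref_aa}>{eff.alt_aa}"
            category = "SAP"
        else:
            seq = translate(mutated_cds(eff, cds, tx.strand), code, to_first_stop=True)
            header_tail = f"{eff.cds_position}:{v.ref_allele}>{v.alt_allele}"
            category = "INDEL"
        if len(seq) < min_protein_len:
            logger.info(
                "variant %s product on %s below %d aa; suppressed",
                v.variant_id, tx.transcript_id, min_protein_len,
            )
            continue
        accession = f"VAR|{category}|{v.variant_id}|{tx.transcript_id}|{header_tail}"
        entries.append(
            DatabaseEntry(
                accession=accession,
                sequence=seq,
                category=category,
                provenance={
                    "variant_id": v.variant_id,
                    "transcript_id": tx.transcript_id,
                    "cds_position": str(eff.cds_position),
                    "effect": eff.effect_class,
                },
            )
        )
    return entries


def variant_entries_for_annotation(
    variants: List[VariantRecord],
    transcripts: List[TranscriptModel],
    genome: Dict[str, str],
    code: GeneticCode = STANDARD_CODE,
    min_protein_len: int = 7,
) -> List[DatabaseEntry]:
    """Project every variant onto every coding transcript and collect entries."""
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for tx in transcripts:
        if tx.cds_intervals:
            by_chrom.setdefault(tx.chrom, []).append(tx)
    entries: List[DatabaseEntry] = []
    for tx_list in by_chrom.values():
        for tx in tx_list:
            effects = []
            for v in variants:
                if v.chrom != tx.chrom:
                    continue
                eff = project_variant(v, tx, genome, code)
                if eff is not None:
                    effects.append(eff)
            if effects:
                entries.extend(
                    build_variant_entries(effects, tx, genome, code, min_protein_len)
                )
    return entries
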