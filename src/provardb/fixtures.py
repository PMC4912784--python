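"""Synthetic test inputs with planted ground truth.

Generates an internally consistent toy study: a small genome with
multi-exon protein-coding genes on both strands, its GTF annotation and
translated proteome, then RNA-Seq evidence layered on top — coding
nonsynonymous SNVs, coding frameshift INDELs, exon-skipping junctions,
intergenic novel transcripts, de-novo assembled transcripts — and finally a
search-engine-style PSM table with planted true and false matches at a
controlled score separation.

Everything is deterministic under the seed, and a truth manifest records
what was planted so end-to-end tests can measure recovery. Scores and
e-values are coupled exactly as ``evalue = 2**(-score)`` so the score
convention (−log2 e-value) is invertible. The simulated genome stays under
100 kb so a full pipeline run takes seconds.

What this emulates — and what it does not: the generator produces the
pipeline's direct inputs (post-alignment artifacts and search-engine
output), not reads or spectra. PSM scores are drawn from two clean
Gaussians; real search-score distributions are heavier-tailed and
target/decoy overlap is messier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .db_assembly import CustomDatabase, DatabaseEntry
from .reference_model import (
    STANDARD_CODE,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    translate,
    write_gtf,
)
from .variant_peptides import VariantRecord, mutated_cds, project_variant

logger = logging.getLogger("provardb")

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic run."""

    seed: int = 0
    n_genes: int = 20
    n_snv: int = 15
    n_indel: int = 3
    n_junction: int = 5
    n_novel_tx: int = 5
    n_denovo: int = 2
    n_psms: int = 2000
    psm_true_fraction: float = 0.9
    score_separation: float = 10.0
    novel_psm_fraction: float = 0.05
    true_score_mean: float = 25.0
    score_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_snv", "n_indel", "n_junction", "n_novel_tx",
                     "n_denovo", "n_psms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not (0 < self.psm_true_fraction <= 1):
            raise ValueError("psm_true_fraction must be in (0, 1]")
        if not (0 <= self.novel_psm_fraction <= 1):
            raise ValueError("novel_psm_fraction must be in [0, 1]")


@dataclass
class Reference:
    """In-memory reference generated by :func:`make_reference`."""

    genome: Dict[str, str]
    transcripts: List[TranscriptModel]
    proteome: List[DatabaseEntry]
    cds_by_tx: Dict[str, str]
    dark_regions: List[GenomicInterval]  # intergenic space for novel transcripts


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + body + stop


# ---------------------------------------------------------------------------
# Reference genome / annotation / proteome
# ---------------------------------------------------------------------------

def make_reference(spec: FixtureSpec, outdir=None) -> Reference:
    """Build the toy genome, annotation and proteome.

    Genes carry 1–4 exons (cycled, so multi-exon genes always exist for
    junction planting), alternate strands, and are CDS-complete: ATG start,
    stop end, no internal stops. The proteome is the translated CDS. After
    the genes, intergenic "dark" regions with a planted long ORF are laid
    down as landing sites for novel transcripts.

    When ``outdir`` is given, writes genome.fa, annotation.gtf and
    proteome.fa there.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = "chr1"
    parts: List[str] = []
    cursor = 0

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    transcripts: List[TranscriptModel] = []
    proteome: List[DatabaseEntry] = []
    cds_by_tx: Dict[str, str] = {}

    for i in range(spec.n_genes):
        emit(_random_seq(rng, int(rng.integers(150, 300))))  # spacer
        n_exons = 1 + i % 4
        n_codons = int(rng.integers(40, 100))
        cds = _random_cds(rng, n_codons)
        # split the CDS into exon pieces of ≥ 12 nt
        cuts = sorted(
            rng.choice(np.arange(12, len(cds) - 12), size=n_exons - 1, replace=False)
        ) if n_exons > 1 else []
        pieces = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
        strand = "+" if i % 2 == 0 else "-"
        # lay out pieces with introns, in coding order on the plus-strand layout
        coding_layout = ""
        piece_spans: List[Tuple[int, int]] = []
        for k, piece in enumerate(pieces):
            if k:
                coding_layout += _random_seq(rng, int(rng.integers(30, 80)))
            a = len(coding_layout)
            coding_layout += piece
            piece_spans.append((a, a + len(piece)))
        region = coding_layout if strand == "+" else reverse_complement(coding_layout)
        region_start = emit(region)
        L = len(region)
        exons = []
        for a, b in piece_spans:
            if strand == "+":
                exons.append(GenomicInterval(chrom, region_start + a, region_start + b, strand))
            else:
                exons.append(
                    GenomicInterval(chrom, region_start + L - b, region_start + L - a, strand)
                )
        exons.sort(key=lambda iv: iv.start)
        tid, gid = f"TX{i:03d}", f"GENE{i:03d}"
        tx = TranscriptModel(tid, gid, exons, cds_intervals=list(exons), strand=strand)
        transcripts.append(tx)
        cds_by_tx[tid] = cds
        protein = translate(cds, STANDARD_CODE, to_first_stop=True)
        proteome.append(
            DatabaseEntry(f"PROT{i:03d}", protein, "REF", {"gene": gid, "tx": tid})
        )

    dark_regions: List[GenomicInterval] = []
    for _ in range(max(spec.n_novel_tx, spec.n_denovo)):
        emit(_random_seq(rng, int(rng.integers(150, 250))))
        # planted stop-free ORF guarantees translatable novel products
        planted = _random_cds(rng, int(rng.integers(40, 70)))
        start = emit(planted + _random_seq(rng, int(rng.integers(40, 80))))
        dark_regions.append(
            GenomicInterval(chrom, start, start + len(planted) + 0, "+")
        )
    emit(_random_seq(rng, 200))

    genome = {chrom: "".join(parts)}
    ref = Reference(genome, transcripts, proteome, cds_by_tx, dark_regions)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta_simple(outdir / "genome.fa", [(chrom, genome[chrom])])
        write_gtf(transcripts, outdir / "annotation.gtf")
        _write_fasta_simple(
            outdir / "proteome.fa", [(e.accession, e.sequence) for e in proteome]
        )
    return ref


def _write_fasta_simple(path, records: List[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Evidence: VCF, junction BED, novel GTF, de-novo FASTA
# ---------------------------------------------------------------------------

def _cds_genomic_positions(tx: TranscriptModel) -> List[int]:
    positions: List[int] = []
    for iv in tx.cds_intervals:
        positions.extend(range(iv.start, iv.end))
    if tx.strand == "-":
        positions.reverse()
    return positions

_COMP = str.maketrans("ACGTN", "TGCAN")


def make_evidence(
    spec: FixtureSpec, reference: Reference, outdir
) -> Dict:
    """Plant SNVs, INDELs, exon-skip junctions and novel transcripts.

    Writes variants.vcf, junctions.bed, novel.gtf and denovo.fa under
    ``outdir`` and returns the truth manifest (also written as
    truth.json). Every planted SNV is nonsynonymous, every INDEL a coding
    frameshift, every junction skips one annotated exon, and every novel
    transcript sits in intergenic space.
    """
    rng = np.random.default_rng(spec.seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_seq = reference.genome["chr1"]
    coding = [tx for tx in reference.transcripts if tx.cds_intervals]

    truth: Dict = {"snv": [], "indel": [], "junction": [], "novel_tx": [],
                   "denovo": []}
    vcf_rows = []

    # --- nonsynonymous SNVs -------------------------------------------------
    for i in range(spec.n_snv):
        for _attempt in range(200):
            tx = coding[int(rng.integers(len(coding)))]
            cds = reference.cds_by_tx[tx.transcript_id]
            n_codons = len(cds) // 3
            codon_i = int(rng.integers(1, n_codons - 1))
            within = int(rng.integers(3))
            off = 3 * codon_i + within
            ref_base = cds[off]
            alt_base = _BASES[int(rng.integers(4))]
            if alt_base == ref_base:
                continue
            ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
            alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
            ref_aa = translate(ref_codon)
            alt_aa = translate(alt_codon)
            if ref_aa == alt_aa or alt_aa == "*" or ref_aa == "*":
                continue
            gpos = _cds_genomic_positions(tx)[off]
            g_ref = genome_seq[gpos]
            g_alt = alt_base if tx.strand == "+" else alt_base.translate(_COMP)
            vid = f"snv{i}"
            vcf_rows.append((gpos + 1, vid, g_ref, g_alt))
            expected = (
                translate(cds, to_first_stop=True)[:codon_i]
                + alt_aa
                + translate(cds, to_first_stop=True)[codon_i + 1 :]
            )
            truth["snv"].append(
                {
                    "variant_id": vid,
                    "transcript_id": tx.transcript_id,
                    "cds_position": off,
                    "ref_aa": ref_aa,
                    "alt_aa": alt_aa,
                    "protein": expected,
                }
            )
            break
        else:
            raise RuntimeError("could not plant a nonsynonymous SNV")

    # --- frameshift deletions ----------------------------------------------
    for i in range(spec.n_indel):
        for _attempt in range(200):
            tx = coding[int(rng.integers(len(coding)))]
            cds = reference.cds_by_tx[tx.transcript_id]
            # anchor + deleted base must sit inside one CDS exon, mid-protein
            gpos_list = _cds_genomic_positions(tx)
            off = int(rng.integers(9, len(cds) - 12))
            g_anchor, g_next = gpos_list[off], gpos_list[off + 1]
            if abs(g_next - g_anchor) != 1:  # exon boundary between them
                continue
            lo = min(g_anchor, g_next)
            ref_alleles = genome_seq[lo : lo + 2]
            alt_allele = genome_seq[lo]
            vid = f"indel{i}"
            v = VariantRecord("chr1", lo + 1, ref_alleles, alt_allele, vid)
            eff = project_variant(v, tx, reference.genome)
            if eff is None or eff.effect_class != "frameshift":
                continue
            expected = translate(
                mutated_cds(eff, cds, tx.strand), to_first_stop=True
            )
            if len(expected) < 7:
                continue
            vcf_rows.append((lo + 1, vid, ref_alleles, alt_allele))
            truth["indel"].append(
                {
                    "variant_id": vid,
                    "transcript_id": tx.transcript_id,
                    "protein": expected,
                }
            )
            break
        else:
            raise RuntimeError("could not plant a frameshift INDEL")

    # --- exon-skipping junctions -------------------------------------------
    multi = [tx for tx in reference.transcripts if len(tx.intervals) >= 3]
    for i in range(spec.n_junction):
        tx = multi[i % len(multi)]
        k = int(rng.integers(len(tx.intervals) - 2))
        left, right = tx.intervals[k], tx.intervals[k + 2]
        name = f"JUNC{i}"
        truth["junction"].append(
            {
                "name": name,
                "transcript_id": tx.transcript_id,
                "left_end": left.end,
                "right_start": right.start,
            }
        )
        vcf_rows  # no-op; keeps structure parallel
        tx_strand = tx.strand
        truth["junction"][-1]["strand"] = tx_strand

    # --- intergenic novel transcripts (GTF) ---------------------------------
    novel_models: List[TranscriptModel] = []
    for i in range(spec.n_novel_tx):
        region = reference.dark_regions[i % len(reference.dark_regions)]
        tid, gid = f"NOVTX{i}", f"NOVG{i}"
        novel_models.append(
            TranscriptModel(
                tid, gid,
                [GenomicInterval(region.chrom, region.start, region.end, "+")],
                cds_intervals=[], strand="+",
            )
        )
        truth["novel_tx"].append(
            {"transcript_id": tid, "start": region.start, "end": region.end}
        )

    # --- de-novo assembled transcripts (FASTA) ------------------------------
    rng_dn = np.random.default_rng(spec.seed + 2)
    denovo_records: List[Tuple[str, str]] = []
    for i in range(spec.n_denovo):
        planted = _random_cds(rng_dn, int(rng_dn.integers(40, 60)))
        seq = (
            _random_seq(rng_dn, int(rng_dn.integers(30, 60)))
            + planted
            + _random_seq(rng_dn, int(rng_dn.integers(30, 60)))
        )
        name = f"DNTX{i}"
        denovo_records.append((name, seq))
        truth["denovo"].append({"transcript_id": name, "length": len(seq)})

    # --- write files ---------------------------------------------------------
    with open(outdir / "variants.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={len(genome_seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, vid, ref, alt in sorted(vcf_rows):
            fh.write(f"chr1\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\n")

    with open(outdir / "junctions.bed", "w") as fh:
        for rec in truth["junction"]:
            tx = next(
                t for t in reference.transcripts
                if t.transcript_id == rec["transcript_id"]
            )
            left = next(iv for iv in tx.intervals if iv.end == rec["left_end"])
            right = next(iv for iv in tx.intervals if iv.start == rec["right_start"])
            chrom_start, chrom_end = left.start, right.end
            sizes = f"{len(left)},{len(right)}"
            starts = f"0,{right.start - chrom_start}"
            reads = int(np.random.default_rng(spec.seed + 3).integers(5, 50))
            fh.write(
                f"chr1\t{chrom_start}\t{chrom_end}\t{rec['name']}\t{reads}\t"
                f"{rec['strand']}\t{chrom_start}\t{chrom_end}\t0\t2\t{sizes}\t{starts}\n"
            )

    write_gtf(novel_models, outdir / "novel.gtf")
    _write_fasta_simple(outdir / "denovo.fa", denovo_records)

    truth["counts"] = {
        "n_snv": spec.n_snv,
        "n_indel": spec.n_indel,
        "n_junction": spec.n_junction,
        "n_novel_tx": spec.n_novel_tx,
        "n_denovo": spec.n_denovo,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


# ---------------------------------------------------------------------------
# PSM table with planted truth
# ---------------------------------------------------------------------------

def _novel_windows(
    entry: DatabaseEntry,
    ref_haystack: str,
    var_entries: List[DatabaseEntry],
    length: int = 10,
) -> List[str]:
    """Windows of one evidence entry that are novel and class-unambiguous."""
    out = []
    seq = entry.sequence
    for a in range(0, max(len(seq) - length + 1, 0)):
        w = seq[a : a + length]
        if w in ref_haystack:
            continue
        classes = {e.category for e in var_entries if w in e.sequence}
        if classes == {entry.category}:
            out.append(w)
    return out


def make_psms(
    spec: FixtureSpec, database: CustomDatabase, outdir
) -> Dict:
    """Emit a PSM table with planted-true and planted-false matches.

    True PSMs draw peptides from target entries — canonical reference
    windows plus a ``novel_psm_fraction`` share of class-unambiguous novel
    windows — at scores ~N(true_score_mean, score_sd). False PSMs split
    evenly between decoy windows and low-scoring reference windows at
    scores shifted down by ``score_separation``. E-values are exactly
    ``2**(-score)``. Writes psms.tsv and psm_truth.json under ``outdir``.
    """
    rng = np.random.default_rng(spec.seed + 4)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ref_entries = [e for e in database.targets if e.category == "REF"]
    var_entries = [e for e in database.targets if e.category != "REF"]
    decoy_entries = database.decoys
    if not ref_entries:
        raise ValueError("database has no reference entries")
    ref_haystack = "#" + "#".join(e.sequence for e in ref_entries) + "#"

    n_true = int(round(spec.n_psms * spec.psm_true_fraction))
    n_false = spec.n_psms - n_true
    n_novel = int(round(n_true * spec.novel_psm_fraction)) if var_entries else 0

    # pre-compute usable novel windows per evidence entry, grouped by class
    windows_by_class: Dict[str, List[Tuple[str, str]]] = {}
    for e in var_entries:
        for w in _novel_windows(e, ref_haystack, var_entries):
            windows_by_class.setdefault(e.category, []).append((w, e.accession))
    usable_classes = sorted(windows_by_class)
    if n_novel and not usable_classes:
        raise ValueError("no class-unambiguous novel windows available")

    def ref_window() -> Tuple[str, List[str]]:
        e = ref_entries[int(rng.integers(len(ref_entries)))]
        if len(e.sequence) <= 10:
            w = e.sequence
        else:
            a = int(rng.integers(len(e.sequence) - 10 + 1))
            w = e.sequence[a : a + 10]
        accs = [r.accession for r in ref_entries if w in r.sequence]
        return w, accs

    rows = []
    truth_rows = []

    def add(peptide: str, accs: List[str], score: float, is_true: bool,
            planted_class: Optional[str]) -> None:
        idx = len(rows)
        spectrum = f"spec{idx:05d}"
        evalue = 2.0 ** (-score)
        charge = int(rng.integers(2, 4))
        rows.append((spectrum, peptide, ";".join(accs), evalue, charge))
        truth_rows.append(
            {
                "spectrum": spectrum,
                "peptide": peptide,
                "is_true": is_true,
                "planted_class": planted_class,
            }
        )

    # planted-true novel PSMs: cycle classes so each planted class appears
    for i in range(n_novel):
        cls = usable_classes[i % len(usable_classes)]
        w, acc = windows_by_class[cls][int(rng.integers(len(windows_by_class[cls])))]
        accs = sorted(
            e.accession for e in var_entries if w in e.sequence
        )
        score = float(rng.normal(spec.true_score_mean, spec.score_sd))
        add(w, accs, score, True, cls)

    # planted-true canonical PSMs
    for _ in range(n_true - n_novel):
        w, accs = ref_window()
        score = float(rng.normal(spec.true_score_mean, spec.score_sd))
        add(w, accs, score, True, None)

    # planted-false PSMs: half decoy matches, half random reference windows
    n_decoy_false = n_false // 2 if decoy_entries else 0
    false_mean = spec.true_score_mean - spec.score_separation
    for _ in range(n_decoy_false):
        e = decoy_entries[int(rng.integers(len(decoy_entries)))]
        if len(e.sequence) <= 10:
            w = e.sequence
        else:
            a = int(rng.integers(len(e.sequence) - 10 + 1))
            w = e.sequence[a : a + 10]
        score = float(rng.normal(false_mean, spec.score_sd))
        add(w, [e.accession], score, False, None)
    for _ in range(n_false - n_decoy_false):
        w, accs = ref_window()
        score = float(rng.normal(false_mean, spec.score_sd))
        add(w, accs, score, False, None)

    order = rng.permutation(len(rows))
    with open(outdir / "psms.tsv", "w") as fh:
        fh.write("spectrum\tpeptide\tproteins\tevalue\tcharge\n")
        for i in order:
            spectrum, peptide, accs, evalue, charge = rows[i]
            fh.write(f"{spectrum}\t{peptide}\t{accs}\t{evalue:.8g}\t{charge}\n")

    truth = {
        "psms": truth_rows,
        "n_true": n_true,
        "n_false": n_false,
        "n_novel_true": n_novel,
    }
    with open(outdir / "psm_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
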