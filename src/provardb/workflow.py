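"""End-to-end orchestration: build the database, post-process PSMs, report.

These functions are what the CLI subcommands wrap; tests and scripts call
them directly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import (
    db_assembly,
    junction_peptides,
    novel_transcripts,
    psm_postprocess,
    report,
    variant_peptides,
)
from .novel_transcripts import TranslationPolicy
from .reference_model import STANDARD_CODE, GeneticCode, read_genome, read_gtf

logger = logging.getLogger("provardb")


def build_database(
    genome_path,
    gtf_path,
    proteome_path,
    vcf_path=None,
    junction_bed_path=None,
    novel_gtf_path=None,
    denovo_fasta_path=None,
    out_path=None,
    flank_nt: int = junction_peptides.DEFAULT_FLANK_NT,
    min_junction_reads: int = 0,
    min_protein_len: int = 7,
    mode: str = "auto",
    dedup: bool = True,
    code: GeneticCode = STANDARD_CODE,
) -> db_assembly.CustomDatabase:
    """Compose the customized target+decoy database from all evidence inputs.

    ``mode`` controls novel-transcript translation: 'auto' (three-frame for
    stranded, six-frame otherwise), 'orf' for longest-ORF, or an explicit
    'three_frame'/'six_frame'.
    """
    genome = read_genome(genome_path)
    annotation = read_gtf(gtf_path)
    reference = db_assembly.read_proteome(proteome_path)

    evidence: List[db_assembly.DatabaseEntry] = []
    if vcf_path:
        variants = variant_peptides.read_vcf(vcf_path)
        evidence.extend(
            variant_peptides.variant_entries_for_annotation(
                variants, annotation, genome, code, min_protein_len
            )
        )
    if junction_bed_path:
        junctions = junction_peptides.read_junction_bed(
            junction_bed_path, min_reads=min_junction_reads
        )
        evidence.extend(
            junction_peptides.junction_entries(
                junctions, genome, flank_nt, code, min_protein_len
            )
        )
    policy_mode = {"auto": "three_frame", "orf": "longest_orf"}.get(mode, mode)
    if novel_gtf_path:
        novel = read_gtf(novel_gtf_path)
        evidence.extend(
            novel_transcripts.novel_transcript_entries(
                novel, genome, annotation,
                TranslationPolicy(mode=policy_mode, min_protein_len=min_protein_len),
                code,
            )
        )
    if denovo_fasta_path:
        dn_mode = "six_frame" if policy_mode == "three_frame" else policy_mode
        evidence.extend(
            novel_transcripts.denovo_transcript_entries(
                denovo_fasta_path,
                TranslationPolicy(mode=dn_mode, min_protein_len=min_protein_len),
                code,
            )
        )

    db = db_assembly.assemble(reference, evidence, dedup=dedup)
    db = db_assembly.add_decoys(db)
    if out_path:
        db_assembly.write_fasta(db, out_path)
    return db


def postprocess(
    psm_path,
    database: db_assembly.CustomDatabase,
    outdir=None,
    fdr: float = 0.01,
    dialect: str = "tsv",
    equate_il: bool = False,
) -> Dict:
    """Run the full post-processing chain on a PSM table.

    Returns a dict with the surviving PSMs, thresholds, protein groups and
    run summary; when ``outdir`` is given, writes peptides.tsv,
    proteins.tsv and report.html there.
    """
    psms = psm_postprocess.read_psm_table(psm_path, dialect=dialect)
    reference = [e for e in database.targets if e.category == "REF"]
    var_entries = [e for e in database.targets if e.category != "REF"]
    psm_postprocess.flag_novelty(psms, reference, var_entries, equate_il=equate_il)
    t_canon, t_novel, canonical, novel = psm_postprocess.separate_fdr_filter(
        psms, target_fdr=fdr
    )
    psm_postprocess.classify_novel(novel, var_entries)
    groups = psm_postprocess.infer_proteins(canonical)
    survivors = canonical + novel
    summary = report.build_summary(
        survivors,
        groups,
        thresholds={"canonical": t_canon, "novel": t_novel},
        parameters={
            "fdr": fdr,
            "equate_il": equate_il,
            "dialect": dialect,
            "n_psms_in": len(psms),
        },
    )
    result = {
        "psms": psms,
        "canonical": canonical,
        "novel": novel,
        "groups": groups,
        "thresholds": {"canonical": t_canon, "novel": t_novel},
        "summary": summary,
    }
    if outdir:
        report.write_tables(survivors, groups, outdir)
        report.write_html_report(summary, outdir)
    return result
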