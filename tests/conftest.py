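"""Shared fixtures: a toy genome, random PSM sets, and one full planted-truth
pipeline run reused by the end-to-end tests."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np
import pytest

from provardb.fixtures import FixtureSpec, make_evidence, make_psms, make_reference
from provardb.psm_postprocess import PSM
from provardb.workflow import build_database, postprocess


@pytest.fixture
def toy_genome() -> Dict[str, str]:
    return {"chr1": "ATGCCCGGGTTTAAACCCGGGATGTAA"}


def random_psm_set(seed: int, n: int = 300) -> List[PSM]:
    """Random scored/flagged PSMs: decoys score lower than targets, ~30%
    decoys, ~30% novel."""
    rng = np.random.default_rng(seed)
    psms = []
    for i in range(n):
        is_decoy = rng.random() < 0.3
        is_novel = rng.random() < 0.3
        score = float(rng.normal(8.0 if is_decoy else 12.0, 3.0))
        p = PSM(f"s{i}", "PEPTIDEK", ["REV_X" if is_decoy else "X"], 2.0 ** -score, 2)
        p.is_decoy = is_decoy
        p.is_novel = is_novel
        psms.append(p)
    return psms


@dataclass
class PipelineRun:
    spec: FixtureSpec
    dir: Path
    db: object
    truth: Dict
    psm_truth: Dict
    result: Dict


@pytest.fixture(scope="session")
def planted_run(tmp_path_factory) -> PipelineRun:
    """One full pipeline run on the planted-truth study conditions:
    20 genes, 15 SNVs, 3 INDELs, 5 junctions, 5 novel transcripts,
    2,000 PSMs at score separation 10, filtered at 1% FDR."""
    d = tmp_path_factory.mktemp("planted")
    spec = FixtureSpec(seed=1)
    ref = make_reference(spec, d)
    truth = make_evidence(spec, ref, d)
    db = build_database(
        d / "genome.fa", d / "annotation.gtf", d / "proteome.fa",
        vcf_path=d / "variants.vcf",
        junction_bed_path=d / "junctions.bed",
        novel_gtf_path=d / "novel.gtf",
        denovo_fasta_path=d / "denovo.fa",
        out_path=d / "custom.fa",
    )
    psm_truth = make_psms(spec, db, d)
    result = postprocess(d / "psms.tsv", db, outdir=d / "out", fdr=0.01)
    return PipelineRun(spec, Path(d), db, truth, psm_truth, result)
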