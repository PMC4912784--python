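"""Result tables and a static HTML summary.

Two tab-delimited tables are written — one row per identified peptide and
one per inferred protein group — plus a single self-contained HTML file
with the novel-class breakdown, score-distribution histograms for novel vs
canonical PSMs, and the run parameters. Every number in the HTML is
recomputed from the same objects that produced the TSVs.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .psm_postprocess import PSM, ProteinGroup

PEPTIDE_COLUMNS = (
    "peptide", "class", "gene_status", "best_score", "n_spectra", "accessions",
)
PROTEIN_COLUMNS = ("representative", "members", "n_peptides", "peptides")


@dataclass
class RunSummary:
    """Counts, thresholds and score histograms for one post-processing run."""

    class_counts: Dict[str, int]
    canonical_peptide_count: int
    protein_group_count: int
    thresholds: Dict[str, Optional[float]]
    histogram_edges: List[float]
    canonical_hist: List[int]
    novel_hist: List[int]
    parameters: Dict[str, object] = field(default_factory=dict)

    @property
    def novel_peptide_count(self) -> int:
        return sum(self.class_counts.values())


def _peptide_rows(psms: Sequence[PSM]) -> List[Tuple]:
    by_pep: Dict[str, Dict] = {}
    for p in psms:
        cls = p.novel_class if p.is_novel else "canonical"
        rec = by_pep.setdefault(
            p.peptide,
            {"class": cls, "gene_status": p.gene_status, "best": p.score,
             "n": 0, "accs": set()},
        )
        rec["n"] += 1
        rec["best"] = max(rec["best"], p.score)
        rec["accs"].update(p.protein_accessions)
    rows = [
        (pep, rec["class"], rec["gene_status"], rec["best"], rec["n"],
         ";".join(sorted(rec["accs"])))
        for pep, rec in by_pep.items()
    ]
    rows.sort(key=lambda r: (r[1], -r[3], r[0]))
    return rows


def write_tables(
    psms: Sequence[PSM], groups: Sequence[ProteinGroup], outdir
) -> Tuple[Path, Path]:
    """Write peptides.tsv and proteins.tsv with a deterministic row order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pep_path = outdir / "peptides.tsv"
    with open(pep_path, "w") as fh:
        fh.write("\t".join(PEPTIDE_COLUMNS) + "\n")
        for pep, cls, status, best, n, accs in _peptide_rows(psms):
            fh.write(f"{pep}\t{cls}\t{status}\t{best:.6g}\t{n}\t{accs}\n")
    prot_path = outdir / "proteins.tsv"
    with open(prot_path, "w") as fh:
        fh.write("\t".join(PROTEIN_COLUMNS) + "\n")
        for g in sorted(groups, key=lambda g: g.representative):
            fh.write(
                f"{g.representative}\t{';'.join(g.members)}\t{len(g.peptides)}\t"
                f"{';'.join(sorted(g.peptides))}\n"
            )
    return pep_path, prot_path


def build_summary(
    psms: Sequence[PSM],
    groups: Sequence[ProteinGroup],
    thresholds: Dict[str, Optional[float]],
    parameters: Optional[Dict[str, object]] = None,
    n_bins: int = 20,
) -> RunSummary:
    """Aggregate filtered results into a run summary.

    Class counts are per distinct novel peptide; the histograms are per PSM
    over a shared set of score bins.
    """
    novel_peps: Dict[str, str] = {}
    canonical_peps = set()
    canon_scores, novel_scores = [], []
    for p in psms:
        if p.is_novel:
            novel_peps.setdefault(p.peptide, p.novel_class)
            novel_scores.append(p.score)
        else:
            canonical_peps.add(p.peptide)
            canon_scores.append(p.score)
    class_counts = {c: 0 for c in ("SAP", "INDEL", "JUC", "NTX", "none")}
    for cls in novel_peps.values():
        class_counts[cls] += 1

    all_scores = canon_scores + novel_scores
    if all_scores:
        lo, hi = min(all_scores), max(all_scores)
        if lo == hi:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    canon_hist, _ = np.histogram(canon_scores, bins=edges)
    novel_hist, _ = np.histogram(novel_scores, bins=edges)

    return RunSummary(
        class_counts=class_counts,
        canonical_peptide_count=len(canonical_peps),
        protein_group_count=len(groups),
        thresholds=dict(thresholds),
        histogram_edges=[float(x) for x in edges],
        canonical_hist=[int(x) for x in canon_hist],
        novel_hist=[int(x) for x in novel_hist],
        parameters=dict(parameters or {}),
    )


def _svg_histogram(summary: RunSummary, width: int = 640, height: int = 220) -> str:
    """Tiny inline SVG: paired bars for canonical vs novel PSM scores."""
    n = len(summary.canonical_hist)
    peak = max(summary.canonical_hist + summary.novel_hist + [1])
    bw = width / max(n, 1)
    bars = []
    for i in range(n):
        for series, color, shift in (
            (summary.canonical_hist, "#4878a8", 0.05),
            (summary.novel_hist, "#c44e52", 0.5),
        ):
            h = height * series[i] / peak
            bars.append(
                f'<rect x="{i * bw + bw * shift:.1f}" y="{height - h:.1f}" '
                f'width="{bw * 0.42:.1f}" height="{h:.1f}" fill="{color}"/>'
            )
    lo, hi = summary.histogram_edges[0], summary.histogram_edges[-1]
    return (
        f'<svg width="{width}" height="{height + 24}" '
        f'xmlns="http://www.w3.org/2000/svg">{"".join(bars)}'
        f'<text x="0" y="{height + 16}" font-size="11">score {lo:.1f}</text>'
        f'<text x="{width - 70}" y="{height + 16}" font-size="11">{hi:.1f}</text>'
        "</svg>"
    )


def write_html_report(summary: RunSummary, outdir) -> Path:
    """Render the run summary as one self-contained HTML file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = "".join(
        f"<tr><td>{html.escape(cls)}</td><td>{n}</td></tr>"
        for cls, n in sorted(summary.class_counts.items())
    )
    thresholds = "".join(
        f"<tr><td>{html.escape(k)}</td><td>"
        f"{'n/a' if v is None else f'{v:.4g}'}</td></tr>"
        for k, v in sorted(summary.thresholds.items())
    )
    params = html.escape(json.dumps(summary.parameters, indent=2, sort_keys=True))
    doc = f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>Proteogenomic identification summary</title>
<style>
body {{ font-family: sans-serif; max-width: 56em; margin: 2em auto; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.8em; }}
.legend span {{ padding: 0 0.6em; }}
</style></head><body>
<h1>Proteogenomic identification summary</h1>
<h2>Novel peptides by class</h2>
<table><tr><th>class</th><th>peptides</th></tr>{rows}
<tr><th>total novel</th><th>{summary.novel_peptide_count}</th></tr></table>
<h2>Canonical results</h2>
<p>Canonical peptides: <b>{summary.canonical_peptide_count}</b><br>
Protein groups (minimal list): <b>{summary.protein_group_count}</b></p>
<h2>Score thresholds</h2>
<table><tr><th>scope</th><th>score threshold</th></tr>{thresholds}</table>
<h2>PSM score distribution (&minus;log<sub>2</sub> e-value)</h2>
<p class="legend"><span style="color:#4878a8">&#9632; canonical</span>
<span style="color:#c44e52">&#9632; novel</span></p>
{_svg_histogram(summary)}
<h2>Run parameters</h2>
<pre>{params}</pre>
</body></html>
"""
    path = outdir / "report.html"
    path.write_text(doc)
    return path
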