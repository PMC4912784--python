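"""Post-processing of peptide-spectrum matches against the customized database.

The pipeline here is: parse the search-engine PSM table (best PSM per
spectrum), flag each target peptide as novel when it cannot be mapped into
the reference proteome, estimate false discovery rates separately for the
canonical and novel classes, filter at a nominal FDR (commonly 1%),
classify the surviving novel peptides, and reduce the canonical
identifications to a minimal protein list.

Class-separate FDR for novel peptides
-------------------------------------
Searching reference proteins together with a large evidence-derived search
space makes the global target-decoy FDR anti-conservative for the novel
class. The novel-class estimate used here is

    FDR_n = D+ * (D_n / D) / T_n+

where, over PSMs at or above the score threshold, ``D+`` is the number of
decoy PSMs, ``T_n+`` the number of novel target PSMs, ``D_n`` the number of
decoy PSMs whose decoy entries derive from evidence (VAR) sequences, and
``D`` the total number of decoy PSMs. ``D_n/D`` approximates the fraction
of novel sequences in the search space. The estimate is defined as 0 when
``D`` or ``T_n+`` is 0 and capped at 1.

Scores are ``-log2(e-value)`` throughout, so higher is better.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .db_assembly import DECOY_PREFIX, DatabaseEntry, category_of_accession

logger = logging.getLogger("provardb")

NOVEL_CLASSES = ("SAP", "INDEL", "JUC", "NTX", "none")
GENE_STATUSES = ("existing_gene_variant", "novel_gene_product", "none")

PSM_COLUMNS = ("spectrum", "peptide", "proteins", "evalue", "charge")


@dataclass
class PSM:
    """One peptide-spectrum match (best per spectrum)."""

    spectrum_id: str
    peptide: str
    protein_accessions: List[str]
    evalue: float
    charge: int
    score: float = field(default=0.0)
    is_decoy: bool = False
    is_novel: bool = False
    novel_class: str = "none"
    gene_status: str = "none"
    matched_var_accessions: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"spectrum {self.spectrum_id!r}: e-value must be > 0")
        if not self.score:
            self.score = -math.log2(self.evalue)


@dataclass
class FdrTally:
    """The four counters of the novel-class FDR estimate, at one threshold."""

    D_plus: int = 0
    T_n_plus: int = 0
    D_n: int = 0
    D: int = 0

    def __post_init__(self) -> None:
        if self.D_n > self.D:
            raise ValueError("D_n cannot exceed D")


@dataclass
class ProteinGroup:
    """Proteins indistinguishable by their identified peptide set."""

    representative: str
    members: List[str]
    peptides: Set[str]


# ---------------------------------------------------------------------------
# PSM input
# ---------------------------------------------------------------------------

def _strip_mods(peptide: str) -> str:
    """Reduce a peptide string to its bare residues (drop mod annotations)."""
    return "".join(c for c in peptide.upper() if c.isalpha())


def _best_per_spectrum(psms: List[PSM]) -> List[PSM]:
    best: Dict[str, PSM] = {}
    for p in psms:
        cur = best.get(p.spectrum_id)
        if (
            cur is None
            or p.evalue < cur.evalue
            or (p.evalue == cur.evalue and p.peptide < cur.peptide)
        ):
            best[p.spectrum_id] = p
    return list(best.values())


def read_psm_table(
    path, dialect: str = "tsv", decoy_prefix: str = DECOY_PREFIX
) -> List[PSM]:
    """Read search-engine PSMs from a TSV table or an mzIdentML subset.

    TSV columns (tab-separated): spectrum, peptide, proteins (;-separated
    accessions), evalue, charge. The decoy flag is set when every matched
    accession carries the decoy prefix; one best (lowest e-value) PSM is
    kept per spectrum.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"spectrum": str})
        missing = [c for c in PSM_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing PSM columns {missing}")
        psms = []
        for row in df.itertuples(index=False):
            accessions = [a for a in str(row.proteins).split(";") if a]
            evalue = float(row.evalue)
            if evalue <= 0:
                raise ValueError(
                    f"{path}: spectrum {row.spectrum!r} has e-value {evalue} ≤ 0"
                )
            psms.append(
                PSM(
                    spectrum_id=str(row.spectrum),
                    peptide=_strip_mods(str(row.peptide)),
                    protein_accessions=accessions,
                    evalue=evalue,
                    charge=int(row.charge),
                    is_decoy=all(a.startswith(decoy_prefix) for a in accessions),
                )
            )
    elif dialect == "mzident_subset":
        psms = _read_mzid(path, decoy_prefix)
    else:
        raise ValueError(f"unknown PSM dialect {dialect!r}")
    return _best_per_spectrum(psms)


def _read_mzid(path, decoy_prefix: str) -> List[PSM]:
    """Minimal mzIdentML 1.1 subset reader.

    Covers SpectrumIdentificationResult/Item elements with rank-1 items, a
    PeptideSequence, PeptideEvidence→DBSequence protein accessions and an
    e-value/expect cvParam. Namespace-agnostic by matching on local names.
    """
    from lxml import etree

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    tree = etree.parse(str(path))
    root = tree.getroot()
    peptides: Dict[str, str] = {}
    evidence: Dict[str, Tuple[str, str]] = {}  # id -> (peptide_ref, dbseq_ref)
    dbseqs: Dict[str, str] = {}
    for el in root.iter():
        name = local(el.tag)
        if name == "Peptide":
            seqs = [c.text for c in el if local(c.tag) == "PeptideSequence"]
            if seqs and seqs[0]:
                peptides[el.get("id")] = seqs[0].strip()
        elif name == "PeptideEvidence":
            evidence[el.get("id")] = (
                el.get("peptide_ref", ""), el.get("dBSequence_ref", "")
            )
        elif name == "DBSequence":
            dbseqs[el.get("id")] = el.get("accession", el.get("id"))

    psms: List[PSM] = []
    for result in root.iter():
        if local(result.tag) != "SpectrumIdentificationResult":
            continue
        spectrum_id = result.get("spectrumID") or result.get("id")
        for item in result:
            if local(item.tag) != "SpectrumIdentificationItem":
                continue
            if int(item.get("rank", "1")) != 1:
                continue
            peptide = peptides.get(item.get("peptide_ref", ""))
            accessions: List[str] = []
            evalue: Optional[float] = None
            for child in item:
                cname = local(child.tag)
                if cname == "PeptideEvidenceRef":
                    ev = evidence.get(child.get("peptideEvidence_ref", ""))
                    if ev:
                        acc = dbseqs.get(ev[1])
                        if acc:
                            accessions.append(acc)
                elif cname == "cvParam":
                    pname = (child.get("name") or "").lower()
                    if "e-value" in pname or "expect" in pname:
                        evalue = float(child.get("value"))
            if peptide is None or evalue is None or not accessions:
                continue
            psms.append(
                PSM(
                    spectrum_id=str(spectrum_id),
                    peptide=_strip_mods(peptide),
                    protein_accessions=accessions,
                    evalue=evalue,
                    charge=int(item.get("chargeState", "0")),
                    is_decoy=all(a.startswith(decoy_prefix) for a in accessions),
                )
            )
    return psms


# ---------------------------------------------------------------------------
# Novelty mapping
# ---------------------------------------------------------------------------

def _fold_il(s: str) -> str:
    return s.replace("I", "L")


def flag_novelty(
    psms: List[PSM],
    reference_proteome: List[DatabaseEntry],
    var_entries: Optional[List[DatabaseEntry]] = None,
    equate_il: bool = False,
    decoy_prefix: str = DECOY_PREFIX,
) -> List[PSM]:
    """Mark each target PSM novel when its peptide is absent from the
    reference proteome.

    A peptide maps to the reference when it is an exact substring of any
    reference protein (after I→L folding when ``equate_il``). Novel
    peptides inherit their class from the categories of the VAR entries
    they match; a multi-category match stays class 'none'. A novel peptide
    matching no database entry at all is an input inconsistency and raises.

    Decoy PSMs are 'novel' when any of their decoy entries derives from a
    VAR (evidence) sequence — that drives the D_n counter.
    """
    haystack = "#" + "#".join(e.sequence for e in reference_proteome) + "#"
    if equate_il:
        haystack = _fold_il(haystack)
    var_entries = var_entries or []
    for p in psms:
        if p.is_decoy:
            p.is_novel = any(
                a.startswith(decoy_prefix + "VAR|") for a in p.protein_accessions
            )
            continue
        pep = _fold_il(p.peptide) if equate_il else p.peptide
        p.is_novel = pep not in haystack
        if p.is_novel:
            matches = []
            for e in var_entries:
                seq = _fold_il(e.sequence) if equate_il else e.sequence
                if pep in seq:
                    matches.append(e)
            if not matches:
                raise ValueError(
                    f"peptide {p.peptide!r} (spectrum {p.spectrum_id!r}) maps to "
                    "neither the reference proteome nor any evidence entry; "
                    "PSM table and database are inconsistent"
                )
            p.matched_var_accessions = sorted(e.accession for e in matches)
            classes = {e.category for e in matches}
            p.novel_class = classes.pop() if len(classes) == 1 else "none"
        else:
            p.novel_class = "none"
            p.matched_var_accessions = []
    return psms


# ---------------------------------------------------------------------------
# FDR estimation and filtering
# ---------------------------------------------------------------------------

def novel_fdr(psms: Sequence[PSM], threshold_score: float) -> Tuple[FdrTally, float]:
    """Novel-class FDR at one score threshold.

    Counters run over PSMs with score ≥ threshold. Returns the tally and
    the estimate ``D+ * (D_n/D) / T_n+`` (0 when D or T_n+ is 0; capped
    at 1).
    """
    tally = FdrTally()
    for p in psms:
        if p.score < threshold_score:
            continue
        if p.is_decoy:
            tally.D += 1
            tally.D_plus += 1
            if p.is_novel:
                tally.D_n += 1
        elif p.is_novel:
            tally.T_n_plus += 1
    if tally.D == 0 or tally.T_n_plus == 0:
        return tally, 0.0
    fdr = tally.D_plus * (tally.D_n / tally.D) / tally.T_n_plus
    return tally, min(fdr, 1.0)


def novel_qvalues(
    psms: Sequence[PSM], thresholds: Sequence[float]
) -> List[float]:
    """Monotone (q-value) version of the novel-class FDR curve.

    The raw estimate can rise locally as the threshold tightens (a novel
    target leaves the set while decoy counts persist). The q-value at a
    threshold is the minimum raw estimate over all less-stringent
    thresholds — the quantity one actually filters on — and is
    non-increasing by construction. ``thresholds`` must be ascending.
    """
    out: List[float] = []
    running = math.inf
    for t in thresholds:
        running = min(running, novel_fdr(psms, t)[1])
        out.append(running)
    return out


def global_fdr(psms: Sequence[PSM], threshold_score: float) -> float:
    """Plain target-decoy FDR (D+/T+) at one score threshold."""
    d = t = 0
    for p in psms:
        if p.score < threshold_score:
            continue
        if p.is_decoy:
            d += 1
        else:
            t += 1
    if t == 0:
        return 0.0
    return min(d / t, 1.0)


def filter_at_fdr(
    psms: List[PSM], target_fdr: float = 0.01, class_scope: str = "global"
) -> Tuple[Optional[float], List[PSM]]:
    """Pick the smallest score threshold whose estimated FDR meets the target.

    ``class_scope`` 'global' uses D+/T+ and returns all surviving target
    PSMs; 'novel' uses the class-separate estimate and returns the
    surviving novel target PSMs. When no threshold achieves the target the
    surviving set is empty and a warning is logged.
    """
    if not (0 < target_fdr < 1):
        raise ValueError("target_fdr must be in (0, 1)")
    if class_scope not in ("global", "novel"):
        raise ValueError(f"unknown class_scope {class_scope!r}")

    def n_surviving(t: float) -> int:
        if class_scope == "global":
            return sum(1 for p in psms if not p.is_decoy and p.score >= t)
        return sum(
            1 for p in psms if not p.is_decoy and p.is_novel and p.score >= t
        )

    candidates = sorted({p.score for p in psms})
    chosen: Optional[float] = None
    for t in candidates:  # ascending: first hit is the smallest threshold
        est = (
            global_fdr(psms, t)
            if class_scope == "global"
            else novel_fdr(psms, t)[1]
        )
        # a threshold that keeps no target PSM does not count as achieving
        # the target: the estimate is only vacuously zero there
        if est <= target_fdr and n_surviving(t) > 0:
            chosen = t
            break
    if chosen is None:
        logger.warning(
            "no score threshold reaches FDR ≤ %g in scope %s; empty result",
            target_fdr, class_scope,
        )
        return None, []
    if class_scope == "global":
        survivors = [p for p in psms if not p.is_decoy and p.score >= chosen]
    else:
        survivors = [
            p for p in psms if not p.is_decoy and p.is_novel and p.score >= chosen
        ]
    return chosen, survivors


def separate_fdr_filter(
    psms: List[PSM], target_fdr: float = 0.01
) -> Tuple[Optional[float], Optional[float], List[PSM], List[PSM]]:
    """Filter canonical and novel PSMs at the same nominal FDR with their
    own estimators.

    Returns (canonical threshold, novel threshold, canonical survivors,
    novel survivors).
    """
    t_global, global_survivors = filter_at_fdr(psms, target_fdr, "global")
    canonical = [p for p in global_survivors if not p.is_novel]
    t_novel, novel_survivors = filter_at_fdr(psms, target_fdr, "novel")
    return t_global, t_novel, canonical, novel_survivors


# ---------------------------------------------------------------------------
# Novel-peptide classification
# ---------------------------------------------------------------------------

def classify_novel(
    psms: List[PSM], var_entries: List[DatabaseEntry]
) -> List[PSM]:
    """Assign gene status to novel PSMs.

    A novel peptide uniquely matching SAP/INDEL/JUC entries is a peptide
    variant in an existing gene. One uniquely matching NTX entries is the
    product of a novel gene when none of its source transcripts overlaps an
    annotated gene, otherwise a variant in an existing gene. Matches mixing
    classes stay unclassified and the ambiguity is logged.
    """
    by_acc = {e.accession: e for e in var_entries}
    for p in psms:
        if p.is_decoy or not p.is_novel:
            p.gene_status = "none"
            continue
        matched = [by_acc[a] for a in p.matched_var_accessions if a in by_acc]
        classes = {e.category for e in matched}
        if len(classes) != 1:
            p.gene_status = "none"
            p.novel_class = "none"
            logger.info(
                "peptide %r matches multiple evidence classes %s; unclassified",
                p.peptide, sorted(classes),
            )
            continue
        cls = classes.pop()
        p.novel_class = cls
        if cls in ("SAP", "INDEL", "JUC"):
            p.gene_status = "existing_gene_variant"
        else:  # NTX
            overlaps = any(
                e.provenance.get("gene_overlap") == "1" for e in matched
            )
            p.gene_status = (
                "existing_gene_variant" if overlaps else "novel_gene_product"
            )
    return psms


# ---------------------------------------------------------------------------
# Protein inference (Occam's razor / greedy set cover)
# ---------------------------------------------------------------------------

def infer_proteins(canonical_psms: Sequence[PSM]) -> List[ProteinGroup]:
    """Minimal protein list explaining all identified canonical peptides.

    Greedy set cover: proteins with identical peptide sets merge into one
    group; groups are then selected by most unexplained peptides, ties
    broken by larger total peptide set, then lexicographically smallest
    representative accession.
    """
    pep_to_prots: Dict[str, Set[str]] = {}
    prot_to_peps: Dict[str, Set[str]] = {}
    for p in canonical_psms:
        targets = [a for a in p.protein_accessions if not a.startswith(DECOY_PREFIX)]
        for acc in targets:
            prot_to_peps.setdefault(acc, set()).add(p.peptide)
            pep_to_prots.setdefault(p.peptide, set()).add(acc)
    if not prot_to_peps:
        return []

    # merge indistinguishable proteins
    by_pepset: Dict[frozenset, List[str]] = {}
    for acc, peps in prot_to_peps.items():
        by_pepset.setdefault(frozenset(peps), []).append(acc)
    groups = [
        ProteinGroup(
            representative=min(members),
            members=sorted(members),
            peptides=set(pepset),
        )
        for pepset, members in by_pepset.items()
    ]

    uncovered: Set[str] = set(pep_to_prots)
    selected: List[ProteinGroup] = []
    remaining = list(groups)
    while uncovered:
        remaining.sort(
            key=lambda g: (
                -len(g.peptides & uncovered),
                -len(g.peptides),
                g.representative,
            )
        )
        best = remaining[0]
        gain = best.peptides & uncovered
        if not gain:  # pragma: no cover - cannot happen while uncovered ⊆ ∪groups
            break
        selected.append(best)
        uncovered -= gain
        remaining.remove(best)

    # prune: a group picked early can become redundant once later picks
    # cover its peptides; remove until every group is load-bearing
    pruned = True
    while pruned:
        pruned = False
        for g in sorted(selected, key=lambda g: (len(g.peptides), g.representative)):
            others: Set[str] = set()
            for h in selected:
                if h is not g:
                    others |= h.peptides
            if g.peptides <= others:
                selected.remove(g)
                pruned = True
                break
    return selected
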