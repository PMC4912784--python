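"""Assembly of the customized protein search database.

Merges the reference proteome with all RNA-Seq-derived entries (single
amino acid polymorphisms, INDEL products, splice-junction fragments, novel
transcript products), appends reversed decoys, and writes the final FASTA
with its build manifest.

Header conventions: evidence-derived entries are prefixed ``VAR|<class>|…``
so they can be told apart from reference proteins; decoys are the full
reversed sequence under ``REV_<accession>``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from Bio import SeqIO

logger = logging.getLogger("provardb")

CATEGORIES = ("REF", "SAP", "INDEL", "JUC", "NTX", "DECOY")
DECOY_PREFIX = "REV_"
VAR_PREFIX = "VAR"


@dataclass
class DatabaseEntry:
    """One FASTA record of the search database with provenance metadata."""

    accession: str
    sequence: str
    category: str
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        self.sequence = self.sequence.upper()
        if self.category not in ("REF", "DECOY") and not self.accession.startswith(
            VAR_PREFIX
        ):
            raise ValueError(
                f"evidence entry {self.accession!r} must be VAR-prefixed"
            )


@dataclass
class CustomDatabase:
    """Ordered target+decoy entry list plus a build manifest."""

    entries: List[DatabaseEntry]
    build_manifest: Dict = field(default_factory=dict)

    @property
    def targets(self) -> List[DatabaseEntry]:
        return [e for e in self.entries if e.category != "DECOY"]

    @property
    def decoys(self) -> List[DatabaseEntry]:
        return [e for e in self.entries if e.category == "DECOY"]


def read_proteome(path) -> List[DatabaseEntry]:
    """Read a reference proteome FASTA into REF entries."""
    entries = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate proteome accession {record.id!r}")
        seen.add(record.id)
        entries.append(
            DatabaseEntry(record.id, str(record.seq).upper(), "REF", {"source": "proteome"})
        )
    return entries


def assemble(
    reference: List[DatabaseEntry],
    variants: List[DatabaseEntry],
    dedup: bool = True,
) -> CustomDatabase:
    """Concatenate reference and evidence entries into a target database.

    With ``dedup`` (default on), evidence entries whose sequence occurs as
    an exact substring of any reference protein are dropped — they add no
    novel search space and would bias the novel fraction of the decoy set.
    """
    ref_accs = {e.accession for e in reference}
    var_accs = set()
    for e in variants:
        if e.accession in ref_accs or e.accession in var_accs:
            raise ValueError(f"accession collision: {e.accession!r}")
        var_accs.add(e.accession)

    kept = list(reference)
    dropped = 0
    if dedup:
        # '#' separator prevents matches spanning two proteins
        haystack = "#" + "#".join(e.sequence for e in reference) + "#"
        for e in variants:
            if e.sequence in haystack:
                dropped += 1
            else:
                kept.append(e)
    else:
        kept.extend(variants)

    if dropped:
        logger.info("dedup dropped %d evidence entries matching reference", dropped)

    counts: Dict[str, int] = {}
    for e in kept:
        counts[e.category] = counts.get(e.category, 0) + 1
    manifest = {
        "n_reference": len(reference),
        "n_evidence_in": len(variants),
        "n_evidence_dropped_dedup": dropped,
        "counts_by_category": counts,
        "dedup": dedup,
    }
    return CustomDatabase(entries=kept, build_manifest=manifest)


def add_decoys(db: CustomDatabase, prefix: str = DECOY_PREFIX) -> CustomDatabase:
    """Append one reversed-sequence decoy per target entry.

    Target order is preserved and decoys follow all targets. Palindromic
    sequences (their reversal equals themselves) are still emitted but
    flagged in the manifest. Calling this twice is an error.
    """
    if any(e.category == "DECOY" for e in db.entries):
        raise ValueError("database already contains decoys")
    palindromes = []
    decoys = []
    for e in db.entries:
        rev = e.sequence[::-1]
        if rev == e.sequence:
            palindromes.append(e.accession)
        decoys.append(
            DatabaseEntry(
                accession=prefix + e.accession,
                sequence=rev,
                category="DECOY",
                provenance={"parent": e.accession, "parent_category": e.category},
            )
        )
    manifest = dict(db.build_manifest)
    manifest["n_targets"] = len(db.entries)
    manifest["n_decoys"] = len(decoys)
    manifest["decoy_prefix"] = prefix
    manifest["palindromic_targets"] = palindromes
    return CustomDatabase(entries=db.entries + decoys, build_manifest=manifest)


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(db: CustomDatabase, path) -> None:
    """Write the database as 60-column FASTA plus a JSON manifest.

    The header is the accession followed by serialized provenance
    ``key=value`` pairs. The manifest lands next to the FASTA as
    ``<path>.manifest.json``.
    """
    if not db.entries:
        raise ValueError("refusing to write an empty database")
    accs = [e.accession for e in db.entries]
    if len(accs) != len(set(accs)):
        raise ValueError("duplicate accessions in database")
    with open(path, "w") as fh:
        for e in db.entries:
            meta = " ".join(f"{k}={v}" for k, v in sorted(e.provenance.items()))
            header = f">{e.accession} category={e.category}"
            if meta:
                header += " " + meta
            fh.write(header + "\n" + _wrap(e.sequence) + "\n")
    with open(str(path) + ".manifest.json", "w") as fh:
        json.dump(db.build_manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def category_of_accession(accession: str, decoy_prefix: str = DECOY_PREFIX) -> str:
    """Infer the entry category from a database accession."""
    if accession.startswith(decoy_prefix):
        return "DECOY"
    if accession.startswith(VAR_PREFIX + "|"):
        cls = accession.split("|")[1]
        return cls if cls in CATEGORIES else "NTX"
    return "REF"


def read_database(path, decoy_prefix: str = DECOY_PREFIX) -> CustomDatabase:
    """Read a written database FASTA back, recovering categories and provenance."""
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        prov: Dict[str, str] = {}
        for token in record.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                prov[k] = v
        category = prov.pop("category", None) or category_of_accession(
            record.id, decoy_prefix
        )
        entries.append(DatabaseEntry(record.id, str(record.seq), category, prov))
    manifest = {}
    try:
        with open(str(path) + ".manifest.json") as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        pass
    return CustomDatabase(entries=entries, build_manifest=manifest)
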