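# Methods

This note documents the models, conventions and numerical choices behind
`provardb`, and what the synthetic study does and does not demonstrate.

## Coordinates and sequence primitives

All internal coordinates are 0-based half-open; GTF/VCF (1-based) and BED
(0-based) are converted at the parser boundary, so no downstream code ever
reasons about coordinate dialects. Translation uses NCBI genetic code
table 1 by default (overridable); codons containing N translate to `X` so
draft assemblies survive, and trailing partial codons are ignored — the
treatment of transcripts with incomplete terminal codons is deliberately
permissive rather than an error. Genome FASTA input uppercases, maps U→T,
collapses IUPAC ambiguity codes to N, and rejects anything else with the
offending position.

## Variant products

Each VCF record is projected onto the spliced CDS of every overlapping
coding transcript, strand-aware (minus-strand alleles are
reverse-complemented into coding space). Effects are classified by
translating the reference and alternate codons. Products:

- missense / stop-loss → one full-length variant protein;
- stop-gain → the truncated protein, kept only at ≥ `min_protein_len`;
- frameshift and in-frame INDELs → translation of the edited CDS through
  the new first stop.

Choices worth knowing:

- Variants are applied **one at a time**; co-occurring variants are not
  haplotype-phased.
- Variants spanning an exon–intron boundary have no well-defined spliced
  product and are dropped with a warning.
- Stop-loss products run to the end of the annotated CDS; we do not extend
  translation into downstream genomic sequence, since the 3' extent of
  read-through is not knowable from the annotation.
- VCF FILTER policy: keep `PASS` and `.` by default; multi-allelic records
  are split, symbolic ALTs skipped with a warning.
- `min_protein_len` (default 7 aa, the usual floor for a detectable
  tryptic peptide) is applied uniformly to every evidence product,
  including frameshift products.

## Junction peptides

For each two-block BED12 junction, up to `flank_nt` (default 66, i.e. up
to 22 aa per side — enough to cover typical tryptic peptides; clipped at
block boundaries) nucleotides on each side of the intron are concatenated
and translated in three frames on the annotated strand, or all six when
unstranded. Translations are cut at stops and a fragment is emitted only
when it genuinely spans the junction: at least one residue whose codon
starts left of the junction and at least one nucleotide beyond it, with
the recorded `junction_offset` strictly inside the fragment. A degenerate
fragment whose only junction evidence is a single codon straddling the
boundary is suppressed — it cannot carry a well-defined offset. Junctions
identical to annotated introns are *not* removed at build time: novelty is
a property of the identified peptide (mappability to the reference
proteome), not of the junction record.

## Novel and de-novo transcripts

Genome-anchored novel transcripts are spliced and translated three-frame
when stranded, six-frame otherwise; de-novo assemblies default to six
frames. All stop-to-stop fragments ≥ `min_protein_len` are emitted (not
only the longest per frame — the cost is a few extra decoy-balanced
entries, the benefit is not missing a real product in a frame with two
open stretches). Alternatively the single longest ORF can be used; an ORF
requires an ATG by default (`orf_requires_start`), ties break to the lower
frame index then the smaller start. Overlap of a novel transcript with any
annotated gene locus is recorded as metadata and decides the later
novel-gene classification; overlapping transcripts are still translated.

## Database assembly

Targets are reference proteins plus all evidence entries; decoys are
full-sequence reversals (`REV_` prefix), one per target, appended after
all targets. Evidence entries whose sequence is an exact substring of a
reference protein are dropped by default: they add no novel search space
but would inflate the novel share of the decoy space (`Dₙ/D`) and bias the
novel-class FDR. Palindromic sequences produce self-identical decoys; they
are emitted and flagged in the build manifest.

## Post-processing

One best (lowest e-value) PSM is kept per spectrum before any estimation —
standard practice, and the convention under which all counters are
defined. A target peptide is **novel** iff its stripped sequence (mods
removed) is not an exact substring of any reference protein; I/L folding
is available but off by default (the two residues are mass-identical, but
sequence-level mapping is the default semantics). A decoy PSM counts as
novel (the `Dₙ` counter) when its decoy entry derives from a VAR entry —
the database records each decoy's parent category precisely so this
assignment is principled rather than heuristic.

All four counters of `FDRₙ = D⁺·(Dₙ/D)/Tₙ⁺` run over PSMs at or above the
threshold; the estimate is defined as 0 when `D` or `Tₙ⁺` is 0 and capped
at 1. The raw estimate is **not** monotone in the threshold (a novel
target can leave the accepted set while decoy counts persist, raising the
ratio); `novel_qvalues` provides the standard monotone running-minimum
curve. Filtering picks the smallest score threshold whose raw estimate
meets the target FDR — provably the same threshold q-value filtering would
pick — and a threshold that retains zero target PSMs does not count as
achieving the target (its estimate is only vacuously zero), so an
unreachable target yields an empty set with a warning. Canonical and novel
PSMs are filtered at the same nominal FDR (default 1 %) with their own
estimators: global `D⁺/T⁺` for the canonical scope, `FDRₙ` for the novel
scope.

Novel peptides uniquely matching SAP/INDEL/JUC entries are *peptide
variants in existing genes*; those uniquely matching NTX entries are
*products of novel genes* when no source transcript overlaps an annotated
gene, and existing-gene variants otherwise. Matches mixing evidence
classes stay unclassified, with the ambiguity logged.

Protein inference is greedy set cover over canonical peptides
(Occam's razor): proteins with identical peptide sets merge into one
group; groups are selected by most unexplained peptides, ties broken by
larger total peptide set then lexicographic accession; a final pruning
pass removes any group whose peptides are fully covered by the rest, so
every reported group is load-bearing. Greedy cover is not guaranteed
minimal in general; on exhaustively enumerable instances (≤ 10 proteins)
it matches the true minimum or exceeds it by at most one group in the
property tests.

## Synthetic study conditions

The fixture generator emulates the pipeline's direct inputs, not raw data:
no reads, no spectra. Default conditions (all overridable): 20 genes of
1–4 exons on both strands on a ~13 kb chromosome, CDS-complete and
stop-free internally; 15 nonsynonymous SNVs, 3 coding frameshift
deletions, 5 exon-skipping junctions, 5 intergenic novel transcripts, 2
de-novo transcripts; 2,000 PSMs with 90 % planted-true, 5 % of the true
PSMs novel, and a score separation of 10 between the true (mean 25, sd 2)
and false (mean 15) Gaussian score components. E-values are exactly
`2^(−score)`, making the score convention invertible. Everything is
deterministic under the seed.

What passing tests on these fixtures shows: the plumbing is consistent
end-to-end (planted variants appear as database entries; planted novel
PSMs survive filtering with their classes intact; the realized false
proportion agrees with the nominal FDR). What it does not show: behavior
under realistic search-score distributions (heavy tails, charge-dependent
score scales), chimeric spectra, modified peptides, homologous gene
families that stress the novelty mapping, or decoy models other than
reversal.

## Known limitations

- No haplotype phasing; no splice-site-disrupting SNV modelling; no
  fusion junctions.
- Novelty mapping is exact substring matching; near-identical paralogs can
  make an evidence peptide technically "novel".
- Protein-level FDR is out of scope; the minimal protein list is reported
  without an error estimate.
- The mzIdentML reader covers the documented subset
  (SpectrumIdentificationResult/Item, peptide sequences, protein
  references, e-value cvParam), not the full standard.
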