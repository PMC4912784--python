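# provardb

Customized proteogenomic search databases from RNA-Seq evidence, and
class-separate FDR post-processing of the resulting peptide-spectrum
matches (PSMs).

## The problem

Database-dependent MS/MS search can only identify peptides that are present
in the search database. Sample-specific sequence variation — single
nucleotide variants, small INDELs, unannotated splice junctions and novel
transcripts observed by RNA-Seq — is invisible to a search against the
reference proteome. `provardb` builds a **customized protein database**
that layers this RNA-Seq evidence on top of the reference proteome, and
then post-processes search-engine PSMs to identify **novel peptides** at a
controlled false discovery rate.

The pipeline has two halves:

1. **Database construction** (`builddb`): reference proteins, plus
   - **SAP** entries — full-length variant proteins for nonsynonymous SNVs,
   - **INDEL** entries — products of coding insertions/deletions translated
     through the new first stop,
   - **JUC** entries — translations spanning exon–exon junctions (three
     frames with strand information, six without),
   - **NTX** entries — stop-to-stop (or longest-ORF) translations of novel
     and de-novo assembled transcripts,
   - one reversed **decoy** per target.
   Evidence-derived entries are FASTA-prefixed `VAR|<class>|…` to
   distinguish them from reference proteins; decoys are `REV_<accession>`.

2. **Post-processing** (`postprocess`): best PSM per spectrum, novelty
   flagging by exact mapping against the reference proteome, **separate FDR
   estimation** for the novel class, filtering (default 1 %), novel-peptide
   classification (peptide variant in an existing gene vs product of a
   novel gene), Occam's-razor protein inference for canonical peptides, and
   TSV + HTML reporting.

### The novel-class FDR

Scores are `−log2(e-value)`. Over PSMs at or above a score threshold, with
`D⁺` the decoy PSM count, `Tₙ⁺` the novel target PSM count, `Dₙ` the decoy
PSMs whose decoy derives from an evidence (VAR) entry and `D` all decoy
PSMs, the novel-class estimate is

```
FDRₙ = D⁺ · (Dₙ / D) / Tₙ⁺
```

`Dₙ/D` approximates the fraction of novel sequences in the search space,
which keeps the estimate honest when the evidence entries vastly outnumber
true novel peptides. Canonical and novel PSMs are filtered at the same
nominal FDR with their own estimators.

## Worked example

Everything below is generated synthetically — no downloads:

```sh
provardb fixtures --seed 7 -o demo/
provardb postprocess --psm demo/psms.tsv --db demo/custom.fa -o demo/out
```

The `fixtures` command writes a toy genome (~13 kb), annotation, proteome,
VCF/BED/GTF/FASTA evidence, the assembled database and a simulated PSM
table; `postprocess` prints:

```
canonical peptides: 837; novel peptides: 77 (SAP 20, INDEL 16, JUC 20, NTX 21); protein groups: 20
```

meaning 837 distinct reference-mappable peptides survived the 1 % FDR
filter, 77 distinct peptides could not be mapped to the reference proteome
and were assigned to their evidence class, and the canonical peptides are
explained by a minimal list of 20 protein groups. `demo/out/` holds
`peptides.tsv`, `proteins.tsv` and a self-contained `report.html` with the
class breakdown and the score distributions of novel vs canonical PSMs.

Variant entry headers are bit-exact
`VAR|SAP|<variant_id>|<transcript_id>|<cds_pos>:<ref_aa>><alt_aa>` (and
`VAR|INDEL|…` with the nucleotide alleles), so every novel identification
is traceable to its genomic evidence.

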