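"""VCF parsing, variant projection onto the CDS, and SAP/INDEL entries."""

import textwrap

import pytest
from Bio.Seq import Seq

from provardb.reference_model import (
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    translate,
)
from provardb.variant_peptides import (
    VariantRecord,
    build_variant_entries,
    mutated_cds,
    project_variant,
    read_vcf,
)

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    """
)


def write_vcf(tmp_path, body):
    p = tmp_path / "v.vcf"
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_snv_line(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t5\trs1\tA\tG\t.\tPASS\t.\n")
        (v,) = read_vcf(p)
        assert (v.chrom, v.pos, v.ref_allele, v.alt_allele) == ("chr1", 5, "A", "G")
        assert v.var_type == "SNV"

    def test_multiallelic_split(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t5\t.\tA\tG,T\t.\tPASS\t.\n")
        recs = read_vcf(p)
        assert [v.alt_allele for v in recs] == ["G", "T"]

    def test_symbolic_alt_skipped(self, tmp_path, caplog):
        p = write_vcf(tmp_path, "chr1\t5\t.\tA\t<DEL>\t.\tPASS\t.\n")
        with caplog.at_level("WARNING", logger="provardb"):
            assert read_vcf(p) == []
        assert "symbolic" in caplog.text

    def test_filter_policy(self, tmp_path):
        body = "chr1\t5\t.\tA\tG\t.\tq10\t.\nchr1\t8\t.\tC\tT\t.\t.\t.\n"
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER.replace(
                "#CHROM",
                '##FILTER=<ID=q10,Description="low qual">\n#CHROM',
            )
            + body
        )
        assert [v.pos for v in read_vcf(p)] == [8]
        assert [v.pos for v in read_vcf(p, keep_filters=None)] == [5, 8]

    def test_indel_types(self, tmp_path):
        p = write_vcf(
            tmp_path, "chr1\t5\t.\tAC\tA\t.\tPASS\t.\nchr1\t9\t.\tA\tATT\t.\tPASS\t.\n"
        )
        types = [v.var_type for v in read_vcf(p)]
        assert types == ["DEL", "INS"]


# ---------------------------------------------------------------------------
# projection fixture: one gene on each strand encoding the same protein
# ---------------------------------------------------------------------------

CDS = "ATGGCCGATAAAGGGTTTCCCTAA"  # MADKGFP*


def make_tx(strand, intron_at=12, chrom="c"):
    """Two-exon transcript whose spliced CDS is ``CDS`` on the given strand.
    Returns (transcript, genome)."""
    intron = "GGGGGGGG"
    left, right = CDS[:intron_at], CDS[intron_at:]
    layout = left + intron + right
    if strand == "+":
        genome = {chrom: "TT" + layout + "AA"}
        e1 = GenomicInterval(chrom, 2, 2 + len(left), "+")
        e2 = GenomicInterval(chrom, 2 + len(left) + len(intron), 2 + len(layout), "+")
    else:
        genome = {chrom: "TT" + reverse_complement(layout) + "AA"}
        e2 = GenomicInterval(chrom, 2, 2 + len(right), "-")
        e1 = GenomicInterval(chrom, 2 + len(right) + len(intron), 2 + len(layout), "-")
    exons = sorted([e1, e2], key=lambda iv: iv.start)
    tx = TranscriptModel("t1", "g1", exons, cds_intervals=exons, strand=strand)
    return tx, genome


def genomic_of_cds_offset(tx, offset):
    positions = []
    for iv in tx.cds_intervals:
        positions.extend(range(iv.start, iv.end))
    if tx.strand == "-":
        positions.reverse()
    return positions[offset]


class TestProjectVariant:
    def test_missense_snv_matches_codon_oracle(self):
        """SNV in codon 2 (GCC→GTC): oracle is translating both codons."""
        tx, genome = make_tx("+")
        g = genomic_of_cds_offset(tx, 4)  # middle base of codon 2
        v = VariantRecord("c", g + 1, "C", "T", "rs1")
        eff = project_variant(v, tx, genome)
        assert eff.effect_class == "missense"
        assert (eff.ref_aa, eff.alt_aa) == (
            str(Seq("GCC").translate()), str(Seq("GTC").translate())
        )
        assert eff.cds_position == 4

    def test_intronic_snv_returns_none(self):
        tx, genome = make_tx("+")
        intron_pos = tx.cds_intervals[0].end  # first intron base
        v = VariantRecord("c", intron_pos + 1, genome["c"][intron_pos], "A", "rs2")
        if v.ref_allele == "A":
            v = VariantRecord("c", intron_pos + 1, "G", "C", "rs2")
        assert project_variant(v, tx, genome) is None

    def test_one_bp_deletion_is_frameshift(self):
        tx, genome = make_tx("+")
        g = genomic_of_cds_offset(tx, 3)
        ref2 = genome["c"][g : g + 2]
        v = VariantRecord("c", g + 1, ref2, ref2[0], "d1")
        eff = project_variant(v, tx, genome)
        assert eff.effect_class == "frameshift"

    def test_boundary_spanning_variant_classified_noncoding(self, caplog):
        tx, genome = make_tx("+")
        last_exon1 = tx.cds_intervals[0].end - 1
        ref = genome["c"][last_exon1 : last_exon1 + 3]  # crosses into the intron
        v = VariantRecord("c", last_exon1 + 1, ref, ref[0], "b1")
        with caplog.at_level("WARNING", logger="provardb"):
            eff = project_variant(v, tx, genome)
        assert eff.effect_class == "noncoding"

    def test_strand_symmetry(self):
        """The same CDS edit through a minus-strand gene yields the same
        protein-level effect as the plus-strand construction."""
        tx_p, genome_p = make_tx("+")
        tx_m, genome_m = make_tx("-")
        off = 7
        ref_base = CDS[off]
        alt_base = "A" if ref_base != "A" else "G"
        gp = genomic_of_cds_offset(tx_p, off)
        vp = VariantRecord("c", gp + 1, ref_base, alt_base, "s1")
        gm = genomic_of_cds_offset(tx_m, off)
        comp = dict(zip("ACGT", "TGCA"))
        vm = VariantRecord("c", gm + 1, comp[ref_base], comp[alt_base], "s1")
        ep = project_variant(vp, tx_p, genome_p)
        em = project_variant(em_v := vm, tx_m, genome_m)
        assert (ep.cds_position, ep.ref_aa, ep.alt_aa, ep.effect_class) == (
            em.cds_position, em.ref_aa, em.alt_aa, em.effect_class
        )

    def test_ref_allele_mismatch_raises(self):
        tx, genome = make_tx("+")
        g = genomic_of_cds_offset(tx, 4)
        wrong = "G" if genome["c"][g] != "G" else "T"
        v = VariantRecord("c", g + 1, wrong, "A", "x1")
        with pytest.raises(ValueError, match="does not match"):
            project_variant(v, tx, genome)


class TestBuildVariantEntries:
    def _entries(self, strand, off, alt_cds_base, min_len=1):
        tx, genome = make_tx(strand)
        g = genomic_of_cds_offset(tx, off)
        ref_g = genome[tx.chrom][g]
        alt_g = alt_cds_base if strand == "+" else dict(zip("ACGT", "TGCA"))[alt_cds_base]
        v = VariantRecord(tx.chrom, g + 1, ref_g, alt_g, "v1")
        eff = project_variant(v, tx, genome)
        return eff, build_variant_entries([eff], tx, genome, min_protein_len=min_len)

    def test_missense_single_substitution(self):
        # codon 2 GCC→GTC gives A→V at protein position 2 of MADKGFP
        eff, entries = self._entries("+", 4, "T")
        (e,) = entries
        assert e.sequence == "MVDKGFP"
        assert e.category == "SAP"
        assert e.accession == "VAR|SAP|v1|t1|4:A>V"

    def test_synonymous_effect_emits_nothing(self):
        # GCC→GCA is still alanine
        eff, entries = self._entries("+", 5, "A")
        assert eff.effect_class == "synonymous" and entries == []

    def test_frameshift_equals_independent_retranslation(self):
        """Oracle: edit the CDS string directly and translate it."""
        tx, genome = make_tx("+")
        g = genomic_of_cds_offset(tx, 6)
        ref2 = genome["c"][g : g + 2]
        v = VariantRecord("c", g + 1, ref2, ref2[0], "d1")
        eff = project_variant(v, tx, genome)
        (e,) = build_variant_entries([eff], tx, genome, min_protein_len=1)
        edited = CDS[:7] + CDS[8:]  # delete one base → shifted frame
        edited = edited[: len(edited) - len(edited) % 3]
        expected = str(Seq(edited).translate(to_stop=True))
        assert e.sequence == expected
        assert e.category == "INDEL"

    def test_missense_hamming_distance_is_one(self):
        ref_protein = translate(CDS, to_first_stop=True)
        for off, alt in ((4, "T"), (10, "C"), (13, "A")):
            eff, entries = self._entries("+", off, alt)
            if eff.effect_class != "missense":
                continue
            (e,) = entries
            diffs = [i for i, (a, b) in enumerate(zip(ref_protein, e.sequence)) if a != b]
            assert diffs == [eff.cds_position // 3]
            assert ref_protein[diffs[0]] == eff.ref_aa
            assert e.sequence[diffs[0]] == eff.alt_aa

    def test_inverse_variant_recovers_reference(self):
        """Applying a variant and then its ref/alt swap is the identity."""
        tx, genome = make_tx("+")
        g = genomic_of_cds_offset(tx, 4)
        v = VariantRecord("c", g + 1, "C", "T", "v1")
        eff = project_variant(v, tx, genome)
        forward = mutated_cds(eff, CDS, "+")
        v_inv = VariantRecord("c", g + 1, "T", "C", "v1r")
        eff_inv = type(eff)(
            eff.transcript_id, eff.cds_position, eff.alt_aa, eff.ref_aa,
            eff.effect_class, v_inv,
        )
        assert mutated_cds(eff_inv, forward, "+") == CDS

    def test_count_conservation(self):
        """Entries emitted = non-synonymous coding effects."""
        tx, genome = make_tx("+")
        effects = []
        for off in range(3, 18):
            g = genomic_of_cds_offset(tx, off)
            ref = genome["c"][g]
            alt = "A" if ref != "A" else "C"
            eff = project_variant(VariantRecord("c", g + 1, ref, alt, f"v{off}"), tx, genome)
            effects.append(eff)
        entries = build_variant_entries(effects, tx, genome, min_protein_len=1)
        nonsyn = [
            e for e in effects
            if e.effect_class not in ("synonymous", "noncoding")
            and not (e.effect_class == "missense" and e.cds_position // 3 >= 7)
        ]
        assert len(entries) == len(nonsyn)
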