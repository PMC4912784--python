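"""PSM parsing, novelty mapping, separate FDR estimation, classification and
protein inference."""

import itertools
import math
import textwrap

import numpy as np
import pytest

from conftest import random_psm_set
from provardb.db_assembly import DatabaseEntry
from provardb.psm_postprocess import (
    FdrTally,
    PSM,
    classify_novel,
    filter_at_fdr,
    flag_novelty,
    global_fdr,
    infer_proteins,
    novel_fdr,
    novel_qvalues,
    read_psm_table,
)

PSM_HEADER = "spectrum\tpeptide\tproteins\tevalue\tcharge\n"


def write_psms(tmp_path, rows):
    p = tmp_path / "psms.tsv"
    p.write_text(PSM_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return p


def psm(spectrum, score, is_decoy=False, is_novel=False, peptide="PEPTIDEK",
        accs=None):
    p = PSM(spectrum, peptide, accs or ["X"], 2.0 ** -score, 2)
    p.is_decoy = is_decoy
    p.is_novel = is_novel
    return p


class TestReadPsmTable:
    def test_score_is_minus_log2_evalue(self, tmp_path):
        p = write_psms(tmp_path, [("s1", "PEPK", "P1", 0.25, 2)])
        (r,) = read_psm_table(p)
        assert r.score == pytest.approx(2.0)

    def test_best_psm_per_spectrum(self, tmp_path):
        p = write_psms(
            tmp_path,
            [("s1", "AAAK", "P1", 1e-3, 2), ("s1", "CCCK", "P2", 1e-5, 2)],
        )
        (r,) = read_psm_table(p)
        assert r.peptide == "CCCK"

    def test_all_decoy_accessions_flags_decoy(self, tmp_path):
        p = write_psms(
            tmp_path,
            [("s1", "AAAK", "REV_P1;REV_V2", 0.1, 2),
             ("s2", "CCCK", "REV_P1;P2", 0.1, 2)],
        )
        rows = {r.spectrum_id: r for r in read_psm_table(p)}
        assert rows["s1"].is_decoy and not rows["s2"].is_decoy

    def test_missing_column_is_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("spectrum\tpeptide\tevalue\tcharge\ns1\tAAA\t0.1\t2\n")
        with pytest.raises(ValueError, match="missing"):
            read_psm_table(p)

    def test_nonpositive_evalue_is_error(self, tmp_path):
        p = write_psms(tmp_path, [("s1", "AAAK", "P1", 0.0, 2)])
        with pytest.raises(ValueError, match="≤ 0|<= 0|must be > 0"):
            read_psm_table(p)

    def test_modification_annotations_are_stripped(self, tmp_path):
        p = write_psms(tmp_path, [("s1", "PEM[+15.995]TK", "P1", 0.1, 2)])
        (r,) = read_psm_table(p)
        assert r.peptide == "PEMTK"


MZID = textwrap.dedent(
    """\
    <?xml version="1.0" encoding="UTF-8"?>
    <MzIdentML id="x" version="1.1.0" xmlns="http://psidev.info/psi/pi/mzIdentML/1.1">
     <SequenceCollection>
      <DBSequence id="DB_1" accession="P1" searchDatabase_ref="SDB"/>
      <Peptide id="PEP_1"><PeptideSequence>ELVISLIVESK</PeptideSequence></Peptide>
      <PeptideEvidence id="PE_1" peptide_ref="PEP_1" dBSequence_ref="DB_1" isDecoy="false"/>
     </SequenceCollection>
     <DataCollection>
      <AnalysisData>
       <SpectrumIdentificationList id="SIL">
        <SpectrumIdentificationResult id="SIR_1" spectrumID="index=1" spectraData_ref="SD">
         <SpectrumIdentificationItem id="SII_1" rank="1" chargeState="2"
             peptide_ref="PEP_1" experimentalMassToCharge="600.0" passThreshold="true">
          <PeptideEvidenceRef peptideEvidence_ref="PE_1"/>
          <cvParam cvRef="PSI-MS" accession="MS:1001330" name="X\\!Tandem:expect" value="0.125"/>
         </SpectrumIdentificationItem>
        </SpectrumIdentificationResult>
       </SpectrumIdentificationList>
      </AnalysisData>
     </DataCollection>
    </MzIdentML>
    """
)


def test_mzident_subset_reader(tmp_path):
    p = tmp_path / "r.mzid"
    p.write_text(MZID)
    (r,) = read_psm_table(p, dialect="mzident_subset")
    assert r.peptide == "ELVISLIVESK"
    assert r.protein_accessions == ["P1"]
    assert r.score == pytest.approx(3.0)  # -log2(0.125)
    assert r.charge == 2


class TestFlagNovelty:
    REF = [DatabaseEntry("P1", "MKRPEPTIDEKDE", "REF")]
    VAR = [DatabaseEntry("VAR|SAP|v1|t1|4:A>V", "MKRPEWTIDEKDE", "SAP")]

    def test_reference_peptide_is_not_novel(self):
        p = psm("s1", 10, peptide="PEPTIDEK", accs=["P1"])
        flag_novelty([p], self.REF, self.VAR)
        assert not p.is_novel

    def test_var_only_peptide_is_novel_with_class(self):
        p = psm("s1", 10, peptide="PEWTIDEK", accs=["VAR|SAP|v1|t1|4:A>V"])
        flag_novelty([p], self.REF, self.VAR)
        assert p.is_novel and p.novel_class == "SAP"

    def test_il_folding_maps_peptide_to_reference(self):
        ref = [DatabaseEntry("P1", "AAPEPTLDEKAA", "REF")]
        p = psm("s1", 10, peptide="PEPTIDEK", accs=["P1"])
        flag_novelty([p], ref, [], equate_il=True)
        assert not p.is_novel
        p2 = psm("s2", 10, peptide="PEPTIDEK", accs=["P1"])
        with pytest.raises(ValueError):
            flag_novelty([p2], ref, [], equate_il=False)

    def test_unmappable_novel_peptide_is_inconsistent_input(self):
        p = psm("s1", 10, peptide="WWWWWWWW", accs=["P1"])
        with pytest.raises(ValueError, match="inconsistent"):
            flag_novelty([p], self.REF, self.VAR)

    def test_decoy_novelty_from_parent_entry(self):
        d1 = psm("s1", 10, is_decoy=True, accs=["REV_VAR|SAP|v1|t1|4:A>V"])
        d2 = psm("s2", 10, is_decoy=True, accs=["REV_P1"])
        flag_novelty([d1, d2], self.REF, self.VAR)
        assert d1.is_novel and not d2.is_novel


class TestNovelFdr:
    def test_direct_substitution(self):
        """D+=10, D_n=2, D=10, T_n+=50 → 10·(2/10)/50 = 0.04."""
        psms = (
            [psm(f"d{i}", 5, is_decoy=True, is_novel=i < 2) for i in range(10)]
            + [psm(f"t{i}", 5, is_novel=True) for i in range(50)]
        )
        tally, fdr = novel_fdr(psms, 0.0)
        assert (tally.D_plus, tally.T_n_plus, tally.D_n, tally.D) == (10, 50, 2, 10)
        assert fdr == pytest.approx(0.04)

    def test_zero_novel_decoys_gives_zero(self):
        psms = [psm("d1", 5, is_decoy=True)] + [psm("t1", 5, is_novel=True)]
        assert novel_fdr(psms, 0.0)[1] == 0.0

    def test_no_decoys_or_no_novel_targets_gives_zero(self):
        assert novel_fdr([psm("t1", 5, is_novel=True)], 0.0)[1] == 0.0
        assert novel_fdr([psm("d1", 5, is_decoy=True, is_novel=True)], 0.0)[1] == 0.0

    def test_matches_brute_force_recount_on_random_sets(self):
        """Literal recount oracle on random PSM sets at many thresholds."""
        for seed in range(20):
            psms = random_psm_set(seed, n=150)
            scores = sorted(p.score for p in psms)
            for t in np.linspace(scores[0] - 1, scores[-1] + 1, 15):
                above = [p for p in psms if p.score >= t]
                D = sum(p.is_decoy for p in above)
                Dn = sum(p.is_decoy and p.is_novel for p in above)
                Tn = sum((not p.is_decoy) and p.is_novel for p in above)
                expected = 0.0 if (D == 0 or Tn == 0) else min(D * (Dn / D) / Tn, 1.0)
                assert novel_fdr(psms, t)[1] == expected

    def test_tally_invariant(self):
        with pytest.raises(ValueError):
            FdrTally(D_plus=1, T_n_plus=1, D_n=3, D=2)


class TestFilterAtFdr:
    def test_all_targets_no_decoys_all_survive(self):
        psms = [psm(f"t{i}", float(i)) for i in range(10)]
        t, surv = filter_at_fdr(psms, 0.01)
        assert len(surv) == 10

    def test_alternating_scores_match_hand_walk(self):
        """Brute-force scan over all candidate thresholds as the oracle."""
        psms = []
        for i in range(20):
            psms.append(psm(f"x{i}", 20.0 - i, is_decoy=(i % 2 == 1)))
        target = 0.34
        candidates = sorted({p.score for p in psms})
        expected = None
        for t in candidates:
            if global_fdr(psms, t) <= target:
                expected = t
                break
        t, surv = filter_at_fdr(psms, target)
        assert t == expected
        assert all(p.score >= t and not p.is_decoy for p in surv)

    def test_unreachable_target_returns_empty_with_warning(self, caplog):
        psms = [psm("t1", 5), psm("d1", 6, is_decoy=True)]
        with caplog.at_level("WARNING", logger="provardb"):
            t, surv = filter_at_fdr(psms, 1e-9)
        assert surv == [] and t is None
        assert "no score threshold" in caplog.text

    def test_raising_target_never_shrinks_survivors(self):
        for seed in range(10):
            psms = random_psm_set(seed, n=200)
            prev = set()
            for target in (0.001, 0.01, 0.05, 0.2, 0.5):
                _, surv = filter_at_fdr(psms, target, "novel")
                ids = {p.spectrum_id for p in surv}
                assert prev <= ids
                prev = ids

    def test_novel_qvalue_curve_is_monotone(self):
        for seed in range(10):
            psms = random_psm_set(seed, n=200)
            ts = np.linspace(0, 25, 40)
            qs = novel_qvalues(psms, ts)
            assert all(a >= b for a, b in zip(qs, qs[1:]))


class TestClassifyNovel:
    SAP = DatabaseEntry("VAR|SAP|v|t|1:A>V", "MKWPEPTIDEK", "SAP")
    NTX_free = DatabaseEntry(
        "VAR|NTX|n1|frame0|frag1", "WWYYPEPTIDEK", "NTX", {"gene_overlap": "0"}
    )
    NTX_over = DatabaseEntry(
        "VAR|NTX|n2|frame0|frag1", "HHYYPEPTIDEK", "NTX", {"gene_overlap": "1"}
    )

    def _novel(self, matches):
        p = psm("s1", 10, is_novel=True)
        p.matched_var_accessions = [e.accession for e in matches]
        return p

    def test_unique_sap_is_existing_gene_variant(self):
        p = self._novel([self.SAP])
        classify_novel([p], [self.SAP, self.NTX_free])
        assert p.gene_status == "existing_gene_variant" and p.novel_class == "SAP"

    def test_unique_ntx_without_overlap_is_novel_gene_product(self):
        p = self._novel([self.NTX_free])
        classify_novel([p], [self.SAP, self.NTX_free])
        assert p.gene_status == "novel_gene_product"

    def test_unique_ntx_with_overlap_is_existing_gene_variant(self):
        p = self._novel([self.NTX_over])
        classify_novel([p], [self.NTX_over])
        assert p.gene_status == "existing_gene_variant"

    def test_multiclass_match_stays_unclassified(self, caplog):
        p = self._novel([self.SAP, self.NTX_free])
        with caplog.at_level("INFO", logger="provardb"):
            classify_novel([p], [self.SAP, self.NTX_free])
        assert p.gene_status == "none" and p.novel_class == "none"


def oracle_min_cover(pep_sets):
    """Exhaustive minimal set cover over protein pep-sets."""
    universe = set().union(*pep_sets.values())
    prots = list(pep_sets)
    for k in range(1, len(prots) + 1):
        for combo in itertools.combinations(prots, k):
            if set().union(*(pep_sets[p] for p in combo)) == universe:
                return k
    return len(prots)


class TestInferProteins:
    def _psms(self, pep_to_prots):
        return [
            psm(f"s{i}", 10, peptide=pep, accs=list(prots))
            for i, (pep, prots) in enumerate(pep_to_prots.items())
        ]

    def test_subsumed_protein_collapses_to_one_group(self):
        groups = infer_proteins(self._psms({"p1": {"A"}, "p2": {"A", "B"}}))
        assert [g.representative for g in groups] == ["A"]

    def test_both_proteins_needed(self):
        """Exhaustive minimal cover on the instance confirms two groups."""
        peps = {"p1": {"A"}, "p2": {"B"}, "p3": {"A", "B"}}
        groups = infer_proteins(self._psms(peps))
        prot_sets = {"A": {"p1", "p3"}, "B": {"p2", "p3"}}
        assert len(groups) == oracle_min_cover(prot_sets) == 2

    def test_indistinguishable_proteins_merge(self):
        groups = infer_proteins(self._psms({"p1": {"A", "B"}, "p2": {"A", "B"}}))
        (g,) = groups
        assert g.members == ["A", "B"]

    def test_cover_and_no_redundancy_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_prot = int(rng.integers(2, 9))
            n_pep = int(rng.integers(2, 15))
            pep_to_prots = {}
            for i in range(n_pep):
                k = int(rng.integers(1, min(n_prot, 3) + 1))
                prots = rng.choice(n_prot, size=k, replace=False)
                pep_to_prots[f"p{i}"] = {f"PR{j}" for j in prots}
            groups = infer_proteins(self._psms(pep_to_prots))
            covered = set().union(*(g.peptides for g in groups))
            assert covered == set(pep_to_prots)
            for g in groups:
                others = set().union(
                    *(h.peptides for h in groups if h is not g), set()
                )
                assert not (g.peptides <= others), "redundant group selected"
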