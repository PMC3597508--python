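import itertools

import numpy as np
import pytest

from splicedup.isoform_engine import (
    _retention_core,
    enumerate_isoforms,
    find_alt_start,
    molecular_weight,
    retention_consequence,
    splice,
    translate,
)
from splicedup.models import (
    ALT3SS_DISTAL,
    ALT3SS_PROXIMAL,
    ALT_START,
    CONSTITUTIVE,
    GeneModel,
    IntronCandidate,
    SpliceDupError,
)
from splicedup.splice_signals import enumerate_introns
from splicedup.synthetic_data import ArchitectureSpec, generate

from helpers import STANDARD_CODE


def make_candidate(donor, branch, acceptors):
    return IntronCandidate(
        donor_pos=donor, branch_pos=branch,
        acceptors=[(a, 0.0) for a in acceptors], donor_score=0.0, branch_score=0.0,
    )


class TestSplice:
    def test_single_intron_removed(self):
        #            0123456789...
        seq = "AAA" + "GTATGTTACTAACCAG" + "CCC"
        gene = GeneModel(id="g", seq=seq)
        cand = make_candidate(3, 9, [18])
        assert splice(gene, cand, 0) == "AAACCC"

    def test_proximal_vs_distal_differ_by_inter_acceptor_segment(self, alt3ss_locus):
        gene = alt3ss_locus.gene
        cand = enumerate_introns(gene, alt3ss_locus.model)[0]
        prox = splice(gene, cand, 0)
        dist = splice(gene, cand, 1)
        a1, a2 = (a for a, _ in cand.acceptors)
        assert len(prox) - len(dist) == a2 - a1
        # removing the intron leaves flanking exonic sequence untouched
        assert prox[: cand.donor_pos] == gene.seq[: cand.donor_pos]
        assert prox[cand.donor_pos :] == gene.seq[a1 + 1 :]

    def test_matches_exon_concatenation_oracle(self):
        rng = np.random.default_rng(3)
        exon1 = "".join(rng.choice(list("ACGT"), size=60))
        exon2 = "".join(rng.choice(list("ACGT"), size=60))
        intron = "GTATGT" + "C" * 24 + "TACTAAC" + "CTTTTTC" + "CAG"
        gene = GeneModel(id="g", seq=exon1 + intron + exon2)
        cand = make_candidate(60, 60 + 30, [60 + len(intron) - 1])
        assert splice(gene, cand, 0) == exon1 + exon2

    def test_bad_acceptor_index(self):
        gene = GeneModel(id="g", seq="A" * 50)
        with pytest.raises(SpliceDupError):
            splice(gene, make_candidate(1, 10, [40]), 2)


class TestTranslate:
    def test_start_stop(self):
        assert translate("ATGTAA", 1) == "M"

    def test_ctg_codon_is_the_only_difference_between_tables(self):
        assert translate("ATGCTGTAA", 1) == "ML"
        assert translate("ATGCTGTAA", 12) == "MS"
        diffs = []
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            if STANDARD_CODE[codon] == "*":
                continue
            if translate(codon + "TAA", 1)[:1] != translate(codon + "TAA", 12)[:1]:
                diffs.append(codon)
        assert diffs == ["CTG"]

    def test_table1_matches_published_standard_code(self):
        for codon, aa in STANDARD_CODE.items():
            got = translate("ATG" + codon + "GGGTAA", 1)
            if aa == "*":
                assert got == "M"
            else:
                assert got == "M" + aa + "G"

    def test_short_and_ragged_input(self):
        assert translate("AT", 1) == ""
        assert translate("ATGGGAA", 1) == "MG"

    def test_unsupported_table(self):
        with pytest.raises(SpliceDupError):
            translate("ATG", 5)


class TestMolecularWeight:
    def test_empty_is_an_error(self):
        with pytest.raises(SpliceDupError):
            molecular_weight("")

    def test_mg_matches_published_residue_masses(self):
        # Met 131.20 + Gly 57.05 + water 18.02 = 206.27 Da
        assert molecular_weight("MG") * 1000 == pytest.approx(206.27, abs=0.1)

    def test_additivity_up_to_one_water(self):
        a, b = "MGKLY", "TRWQE"
        got = molecular_weight(a + b)
        assert got == pytest.approx(molecular_weight(a) + molecular_weight(b) - 18.02 / 1000, abs=1e-4)

    def test_unknown_residue_named(self):
        with pytest.raises(SpliceDupError, match="X"):
            molecular_weight("MXG")


class TestRetentionRule:
    def host(self, intron):
        # ATG + phase-0 intron + GGG TAA
        return "ATG" + intron + "GGGTAA"

    def test_frame_preserving_stop_free(self):
        gene = GeneModel(id="g", seq=self.host("GTATGTCAG"), cds_start=0)
        cand = make_candidate(3, 4, [11])
        rc = retention_consequence(gene, cand)
        assert rc.frame_preserving and rc.stop_free and rc.functional_retention

    def test_length_not_multiple_of_three(self):
        gene = GeneModel(id="g", seq=self.host("GTATGTCCAG"), cds_start=0)
        rc = retention_consequence(gene, make_candidate(3, 4, [12]))
        assert not rc.frame_preserving and not rc.functional_retention

    def test_in_frame_stop(self):
        gene = GeneModel(id="g", seq=self.host("GTATAGCAG"), cds_start=0)
        rc = retention_consequence(gene, make_candidate(3, 4, [11]))
        assert rc.frame_preserving and not rc.stop_free and not rc.functional_retention

    def test_intron_upstream_of_start_is_out_of_scope(self):
        gene = GeneModel(id="g", seq="GTATGTCAG" + "ATGTAA", cds_start=9)
        with pytest.raises(SpliceDupError):
            retention_consequence(gene, make_candidate(0, 1, [8]))

    def test_exhaustive_truth_table_short_introns(self):
        # all phase-0 GT..AG introns of length <= 9 against the written-out rule
        for length in range(4, 10):
            for middle in itertools.product("ACGT", repeat=length - 4):
                intron = "GT" + "".join(middle) + "AG"
                mrna = "ATG" + intron + "GGGTAA"
                rc = _retention_core(mrna, 0, 3, 3 + length)
                codons = [intron[i : i + 3] for i in range(0, len(intron) - 2, 3)]
                want = length % 3 == 0 and all(STANDARD_CODE[c] != "*" for c in codons)
                assert rc.functional_retention == want, intron


class TestEnumerateIsoforms:
    def test_two_acceptors_retention_ineligible_gives_two_isoforms(self, alt3ss_locus):
        gene = alt3ss_locus.gene
        introns = enumerate_introns(gene, alt3ss_locus.model)
        isoforms = enumerate_isoforms(gene, introns)
        assert [i.event for i in isoforms] == [ALT3SS_PROXIMAL, ALT3SS_DISTAL]

    def test_no_introns_gives_single_constitutive(self):
        gene = GeneModel(id="g", seq="ATGGGATTTAAGTAA", cds_start=0)
        isoforms = enumerate_isoforms(gene, [])
        assert [i.event for i in isoforms] == [CONSTITUTIVE]
        assert isoforms[0].protein == "MGFK"

    def test_seven_intron_gene_yields_two_spliced_isoforms(self):
        locus = generate(ArchitectureSpec(kind="MULTI_INTRON_ALT3SS", seed=2, n_introns=7))
        introns = enumerate_introns(locus.gene, locus.model)
        assert len(introns) == 7
        assert sum(c.alternative for c in introns) == 1
        isoforms = enumerate_isoforms(locus.gene, introns)
        assert sorted(i.event for i in isoforms) == [ALT3SS_DISTAL, ALT3SS_PROXIMAL]

    def test_spliced_length_bookkeeping(self, alt3ss_locus):
        gene = alt3ss_locus.gene
        introns = enumerate_introns(gene, alt3ss_locus.model)
        for iso in enumerate_isoforms(gene, introns):
            removed = sum(
                c.intron_interval(iso.event_detail.get("acceptor", 0))[1]
                - c.intron_interval(iso.event_detail.get("acceptor", 0))[0]
                for c in introns
            )
            assert len(iso.mrna) == len(gene.seq) - removed

    def test_distal_message_shorter_but_protein_shorter_too(self, alt3ss_locus):
        # the long PROTEIN comes from the PROXIMAL site: S1/S2 sit between the sites
        gene = alt3ss_locus.gene
        isoforms = enumerate_isoforms(gene, enumerate_introns(gene, alt3ss_locus.model))
        by_event = {i.event: i for i in isoforms}
        prox, dist = by_event[ALT3SS_PROXIMAL], by_event[ALT3SS_DISTAL]
        assert len(dist.mrna) < len(prox.mrna)
        assert dist.length_aa < prox.length_aa


class TestAltStart:
    def test_planted_internal_atg(self, alt_tss_locus):
        gene = alt_tss_locus.gene
        s1_nt = alt_tss_locus.truth.alt_start_nt[gene.id]
        iso = find_alt_start(gene, s1_nt)
        assert iso is not None and iso.event == ALT_START
        assert iso.protein.startswith("M")
        # S1's consensus begins with Met; the next residues are S1 residues
        from splicedup.motif_classifier import load_motif_models, scan_motifs

        hits = scan_motifs(iso.protein, load_motif_models())
        s1 = [h for h in hits if h.motif_id == "S1"]
        assert s1 and s1[0].start == 0

    def test_non_atg_site_gives_no_isoform(self):
        gene = GeneModel(id="g", seq="ATGGTTAGCTAA", cds_start=0)
        assert find_alt_start(gene, 3) is None  # GTT, not ATG

    def test_alt_start_protein_is_suffix_of_inframe_readthrough(self):
        # same frame, no intervening stop: the short product is a suffix
        seq = "ATGGGA" + "ATGAAACCCGGG" + "TAA"
        gene = GeneModel(id="g", seq=seq, cds_start=0)
        iso = find_alt_start(gene, 6)
        long_protein = translate(seq, 1)
        assert long_protein.endswith(iso.protein)
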