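import itertools

from splicedup.models import DUAL, HBS1_LIKE, MITOCHONDRIAL, NUCLEAR_ENVELOPE, SKI7_LIKE, GeneModel
from splicedup.splice_signals import enumerate_introns
from splicedup.subfun_caller import (
    INCOMPLETE_PARTITION,
    LOCALIZATION_AXIS,
    NOT_COMPARABLE,
    REDUNDANT,
    SUBFUNCTIONALIZED,
    call_subfunctionalization,
    detect_exon_loss_new_start,
    detect_precise_intron_loss,
)


class TestVerdicts:
    def test_classic_partition(self):
        rep = call_subfunctionalization([SKI7_LIKE, HBS1_LIKE], SKI7_LIKE, HBS1_LIKE)
        assert rep.verdict == SUBFUNCTIONALIZED

    def test_dual_ancestor_long_isoform_still_partitions(self):
        # the pre-duplication long isoform carries the full motif complement
        rep = call_subfunctionalization([DUAL, HBS1_LIKE], SKI7_LIKE, HBS1_LIKE)
        assert rep.verdict == SUBFUNCTIONALIZED

    def test_redundant_pair(self):
        rep = call_subfunctionalization([DUAL, HBS1_LIKE], DUAL, DUAL)
        assert rep.verdict == REDUNDANT

    def test_same_function_twice_is_incomplete(self):
        rep = call_subfunctionalization([SKI7_LIKE, HBS1_LIKE], SKI7_LIKE, SKI7_LIKE)
        assert rep.verdict == INCOMPLETE_PARTITION

    def test_one_paralog_still_dual_is_incomplete(self):
        rep = call_subfunctionalization([DUAL, HBS1_LIKE], DUAL, HBS1_LIKE)
        assert rep.verdict == INCOMPLETE_PARTITION

    def test_single_class_ancestor_not_comparable(self):
        rep = call_subfunctionalization([HBS1_LIKE, HBS1_LIKE], SKI7_LIKE, HBS1_LIKE)
        assert rep.verdict == NOT_COMPARABLE

    def test_localization_axis(self):
        rep = call_subfunctionalization(
            [MITOCHONDRIAL, NUCLEAR_ENVELOPE], NUCLEAR_ENVELOPE, MITOCHONDRIAL,
            axis=LOCALIZATION_AXIS,
        )
        assert rep.verdict == SUBFUNCTIONALIZED

    def test_symmetric_under_paralog_swap(self):
        classes = [DUAL, SKI7_LIKE, HBS1_LIKE, "NEITHER"]
        for c1, c2 in itertools.product(classes, repeat=2):
            a = call_subfunctionalization([DUAL, HBS1_LIKE], c1, c2)
            b = call_subfunctionalization([DUAL, HBS1_LIKE], c2, c1)
            assert a.verdict == b.verdict


class TestPreciseIntronLoss:
    def setup_method(self):
        import numpy as np

        rng = np.random.default_rng(9)
        self.exon1 = "".join(rng.choice(list("ACGT"), size=80))
        self.exon2 = "".join(rng.choice(list("ACGT"), size=80))
        self.intron = "GTATGT" + "C" * 30 + "TACTAAC" + "TTTTTTTT" + "CAG"
        self.gene = GeneModel(id="anc", seq=self.exon1 + self.intron + self.exon2)
        from splicedup.models import IntronCandidate

        self.cand = IntronCandidate(
            donor_pos=80, branch_pos=80 + 36,
            acceptors=[(80 + len(self.intron) - 1, 0.0)],
            donor_score=0.0, branch_score=0.0,
        )

    def test_excised_paralog_detected(self):
        flag, ev = detect_precise_intron_loss(self.gene, self.cand, self.exon1 + self.exon2)
        assert flag and ev["mismatches"] == 0

    def test_retained_paralog_not_detected(self):
        flag, _ = detect_precise_intron_loss(self.gene, self.cand, self.gene.seq)
        assert not flag

    def test_mismatch_tolerance_boundary(self):
        paralog = list(self.exon1 + self.exon2)
        # three substitutions across the junction probe (12 nt each side)
        for off in (75, 78, 83):
            paralog[off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[paralog[off]]
        paralog = "".join(paralog)
        flag2, ev2 = detect_precise_intron_loss(self.gene, self.cand, paralog, max_mismatches=2)
        flag3, ev3 = detect_precise_intron_loss(self.gene, self.cand, paralog, max_mismatches=3)
        assert not flag2 and ev2["mismatches"] == 3
        assert flag3

    def test_short_flank_shrinks_probe(self):
        gene = GeneModel(id="a", seq="ACGTA" + self.intron + self.exon2)
        from splicedup.models import IntronCandidate

        cand = IntronCandidate(5, 5 + 36, [(5 + len(self.intron) - 1, 0.0)], 0.0, 0.0)
        flag, ev = detect_precise_intron_loss(gene, cand, "ACGTA" + self.exon2)
        assert flag and ev["k"] == 5


class TestExonLossNewStart:
    def _ancestor_hits(self, motif_models, protein):
        from splicedup.motif_classifier import scan_motifs

        return scan_motifs(protein, motif_models)

    def test_truncation_to_s1_detected(self, wgd_locus, motif_models):
        anc, p1, p2 = wgd_locus.genes
        from splicedup.isoform_engine import enumerate_isoforms
        from splicedup.motif_classifier import scan_motifs

        isoforms = enumerate_isoforms(anc, enumerate_introns(anc, wgd_locus.model))
        long_iso = max(isoforms, key=lambda i: i.length_aa)
        hits = scan_motifs(long_iso.protein, motif_models)
        flag2, _ = detect_exon_loss_new_start(hits, p2, motif_models)
        flag1, _ = detect_exon_loss_new_start(hits, p1, motif_models)
        assert flag2 is True
        assert flag1 is False

    def test_full_length_copy_not_detected(self, alt3ss_locus, motif_models):
        from splicedup.isoform_engine import enumerate_isoforms
        from splicedup.motif_classifier import scan_motifs

        gene = alt3ss_locus.gene
        isoforms = enumerate_isoforms(gene, enumerate_introns(gene, alt3ss_locus.model))
        long_iso = max(isoforms, key=lambda i: i.length_aa)
        hits = scan_motifs(long_iso.protein, motif_models)
        # "paralog" = the proximal-spliced gene itself: S1 is internal, far from the start
        paralog = GeneModel(id="p", seq=long_iso.mrna, cds_start=gene.cds_start)
        flag, ev = detect_exon_loss_new_start(hits, paralog, motif_models)
        assert flag is False

    def test_offset_threshold(self, motif_models):
        s1 = motif_models["S1"].consensus
        s3 = motif_models["S3"].consensus
        ancestor_protein = "M" + "G" * 50 + s1 + "G" * 10 + s3 + "G" * 10
        hits = self._ancestor_hits(motif_models, ancestor_protein)
        # paralog starting 5 residues upstream of S1
        from splicedup.synthetic_data import _encode
        import numpy as np

        rng = np.random.default_rng(0)
        prot = "M" + "GGGG" + s1 + "G" * 30
        cds = "".join(_encode(rng, prot)) + "TAA"
        paralog = GeneModel(id="p", seq="CCCCCC" + cds, cds_start=6)
        flag3, ev = detect_exon_loss_new_start(hits, paralog, motif_models, d=3)
        flag5, _ = detect_exon_loss_new_start(hits, paralog, motif_models, d=5)
        assert ev["s1_offset_aa"] == 5
        assert flag3 is False and flag5 is True

    def test_no_s1_in_ancestor_is_not_comparable(self, motif_models):
        paralog = GeneModel(id="p", seq="ATGGGTTAA", cds_start=0)
        flag, ev = detect_exon_loss_new_start([], paralog, motif_models)
        assert flag is None
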