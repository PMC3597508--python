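import numpy as np
import pytest

from splicedup.models import DUAL, HBS1_LIKE, NEITHER, SKI7_LIKE, MotifHit
from splicedup.motif_classifier import (
    MotifModel,
    catalytic_his_ok,
    classify_isoform,
    scan_motifs,
)
from splicedup.models import SpliceDupError


def hit(mid, start=0, special=None):
    return MotifHit(motif_id=mid, start=start, score=8.0, max_score=8.0,
                    special_residues=special or {})


def full_hbs1_hits(his="H", start=100):
    hits = [hit("H1", start)]
    for i, g in enumerate(["G1", "G2", "G3", "G4", "G5"]):
        special = {"catalytic_his": his} if g == "G3" else {}
        hits.append(hit(g, start + 50 + 30 * i, special))
    return hits


class TestScanMotifs:
    def test_consensus_protein_hits_at_zero_with_max_score(self, motif_models):
        s1 = motif_models["S1"]
        hits = scan_motifs(s1.consensus + "GGGGG", {"S1": s1})
        assert len(hits) == 1
        assert hits[0].start == 0
        assert hits[0].score == s1.max_score

    def test_hits_reported_in_ascending_position(self, motif_models):
        keep = {k: motif_models[k] for k in ("S1", "S2", "S3")}
        protein = (
            "G" * 10 + keep["S1"].consensus + "G" * 7 + keep["S2"].consensus
            + "G" * 9 + keep["S3"].consensus + "G" * 5
        )
        hits = scan_motifs(protein, keep)
        assert [h.motif_id for h in hits] == ["S1", "S2", "S3"]
        assert [h.start for h in hits] == sorted(h.start for h in hits)

    def test_false_positive_rate_on_shuffled_proteins(self, motif_models, alt3ss_locus):
        from splicedup.isoform_engine import enumerate_isoforms
        from splicedup.splice_signals import enumerate_introns

        gene = alt3ss_locus.gene
        iso = enumerate_isoforms(gene, enumerate_introns(gene, alt3ss_locus.model))[0]
        rng = np.random.default_rng(23)
        residues = np.array(list(iso.protein))
        false_positives = 0
        n_shuffles = 100
        for _ in range(n_shuffles):
            rng.shuffle(residues)
            if scan_motifs("".join(residues), motif_models):
                false_positives += 1
        assert false_positives / n_shuffles < 0.05

    def test_empty_protein_rejected(self, motif_models):
        with pytest.raises(SpliceDupError):
            scan_motifs("", motif_models)


class TestCatalyticHis:
    @pytest.mark.parametrize("residue,expected", [("H", True), ("N", False), ("S", False), ("D", False)])
    def test_substitutions(self, residue, expected):
        assert catalytic_his_ok(hit("G3", special={"catalytic_his": residue})) is expected

    def test_missing_hit_is_an_error(self):
        with pytest.raises(SpliceDupError):
            catalytic_his_ok(None)


class TestClassify:
    def test_full_complement_is_dual(self):
        hits = [hit("S1", 0), hit("S2", 20), hit("S3", 40)] + full_hbs1_hits()
        assert classify_isoform(hits).label == DUAL

    def test_hbs1_like(self):
        assert classify_isoform(full_hbs1_hits()).label == HBS1_LIKE

    def test_ski7_like_with_substituted_his(self):
        hits = [hit("S1", 0), hit("S2", 20), hit("S3", 40)]
        for i, g in enumerate(["G1", "G2", "G3", "G4", "G5"]):
            special = {"catalytic_his": "N"} if g == "G3" else {}
            hits.append(hit(g, 100 + 30 * i, special))
        assert classify_isoform(hits).label == SKI7_LIKE

    def test_no_hits_is_neither(self):
        assert classify_isoform([]).label == NEITHER

    def test_order_invariance(self):
        hits = [hit("S1", 0), hit("S2", 20), hit("S3", 40)] + full_hbs1_hits()
        rng = np.random.default_rng(1)
        for _ in range(10):
            perm = list(hits)
            rng.shuffle(perm)
            assert classify_isoform(perm).label == DUAL

    def test_removing_s1_s2_from_dual_yields_hbs1_like(self):
        hits = [hit("S1", 0), hit("S2", 20), hit("S3", 40)] + full_hbs1_hits()
        assert classify_isoform(hits).label == DUAL
        pruned = [h for h in hits if h.motif_id not in ("S1", "S2")]
        assert classify_isoform(pruned).label == HBS1_LIKE

    def test_ntd_is_supporting_not_required(self):
        hits = full_hbs1_hits()
        assert classify_isoform(hits).label == HBS1_LIKE
        with_ntd = [hit("NTD", 0)] + hits
        assert classify_isoform(with_ntd).label == HBS1_LIKE


class TestPlantedRecovery:
    def test_planted_class_recovery_on_small_suite(self, small_suite, motif_models):
        from splicedup.pipeline import evaluate_locus

        checked = ok = 0
        for _, locus in small_suite.loci:
            if not locus.truth.expected_classes:
                continue
            res = evaluate_locus(locus)
            if "classes" in res["checks"]:
                checked += 1
                ok += res["checks"]["classes"]
        assert checked > 0
        assert ok / checked >= 0.95


class TestMotifModel:
    def test_pattern_sets_and_wildcards(self):
        m = MotifModel(id="X", pattern="G[ST].K", threshold=1.0)
        assert len(m) == 4
        assert m.max_score == 3  # wildcard column unscored
        assert m.score("GSAK") == 3
        assert m.score("GTAK") == 3
        assert m.score("GAAK") == 2

    def test_special_position_not_scored(self, motif_models):
        g3 = motif_models["G3"]
        variant = list(g3.consensus)
        variant[g3.special_positions["catalytic_his"]] = "N"
        assert g3.score("".join(variant)) == g3.max_score

    def test_bad_threshold(self):
        with pytest.raises(SpliceDupError):
            MotifModel(id="X", pattern="AAA", threshold=0.0)
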