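import pytest
from Bio import SeqIO

from splicedup.models import AnalysisReport, Isoform, ParseError
from splicedup.seqio import (
    read_fasta,
    read_gff3,
    read_protein_fasta,
    write_gff3,
    write_isoforms,
)


class TestReadFasta:
    def test_single_record_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">g1\nacgt\n")
        assert read_fasta(p) == [("g1", "ACGT")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_u_mapped_to_t_matches_independent_reparse(self, tmp_path):
        p = tmp_path / "u.fasta"
        p.write_text(">r\nacguACGU\n")
        (rid, seq), = read_fasta(p)
        independent = str(next(SeqIO.parse(str(p), "fasta")).seq).upper().replace("U", "T")
        assert seq == independent == "ACGTACGT"

    def test_illegal_character_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">r\nACGT\nAC!T\n")
        with pytest.raises(ParseError, match="line 3"):
            read_fasta(p)

    def test_sequence_before_header(self, tmp_path):
        p = tmp_path / "head.fasta"
        p.write_text("ACGT\n")
        with pytest.raises(ParseError, match="line 1"):
            read_fasta(p)

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "multi.fasta"
        p.write_text(">b\nAA\n>a\nCC\n")
        assert [r[0] for r in read_fasta(p)] == ["b", "a"]

    def test_protein_reader_accepts_amino_acids(self, tmp_path):
        p = tmp_path / "p.fasta"
        p.write_text(">p1\nMSDFRKLAE\n")
        assert read_protein_fasta(p) == [("p1", "MSDFRKLAE")]


GFF_PLUS = """\
##gff-version 3
chr1\t.\tgene\t1\t9\t.\t+\t.\tID=g1
chr1\t.\tmRNA\t1\t9\t.\t+\t.\tID=g1.m1;Parent=g1
chr1\t.\texon\t1\t6\t.\t+\t.\tParent=g1.m1
chr1\t.\tCDS\t1\t6\t.\t+\t0\tParent=g1.m1
"""

GFF_MINUS = """\
##gff-version 3
chr1\t.\tgene\t1\t6\t.\t-\t.\tID=g1
chr1\t.\tmRNA\t1\t6\t.\t-\t.\tID=g1.m1;Parent=g1
chr1\t.\texon\t1\t3\t.\t-\t.\tParent=g1.m1
chr1\t.\tCDS\t1\t3\t.\t-\t0\tParent=g1.m1
"""

GFF_TWO_MRNAS = """\
##gff-version 3
chr1\t.\tgene\t1\t9\t.\t+\t.\tID=g1
chr1\t.\tmRNA\t1\t9\t.\t+\t.\tID=g1.m1;Parent=g1
chr1\t.\texon\t1\t9\t.\t+\t.\tParent=g1.m1
chr1\t.\tmRNA\t1\t9\t.\t+\t.\tID=g1.m2;Parent=g1
chr1\t.\texon\t1\t6\t.\t+\t.\tParent=g1.m2
"""


class TestReadGff3:
    def _write(self, tmp_path, gff, fasta_seq):
        g = tmp_path / "in.gff3"
        g.write_text(gff)
        f = tmp_path / "in.fasta"
        f.write_text(f">chr1\n{fasta_seq}\n")
        return g, f

    def test_plus_strand_coordinate_convention(self, tmp_path):
        g, f = self._write(tmp_path, GFF_PLUS, "ATGTAACCC")
        (model,) = read_gff3(g, f)
        assert model.exons == [(0, 6)]
        assert model.cds_start == 0
        assert model.seq == "ATGTAACCC"

    def test_minus_strand_reverse_complemented(self, tmp_path):
        g, f = self._write(tmp_path, GFF_MINUS, "AAACAT")
        (model,) = read_gff3(g, f)
        assert model.seq.startswith("ATG")
        assert model.exons == [(3, 6)]
        assert model.origin["strand"] == "-"

    def test_two_mrnas_share_gene_prefix(self, tmp_path):
        g, f = self._write(tmp_path, GFF_TWO_MRNAS, "ATGTAACCC")
        models = read_gff3(g, f)
        assert len(models) == 2
        assert all(m.id.startswith("g1.") for m in models)
        assert all("no_cds" in m.source for m in models)
        assert all(m.cds_start is None for m in models)

    def test_round_trip_preserves_coordinates_and_strand(self, tmp_path):
        for gff, seq in ((GFF_PLUS, "ATGTAACCC"), (GFF_MINUS, "AAACAT")):
            g, f = self._write(tmp_path, gff, seq)
            (model,) = read_gff3(g, f)
            out = tmp_path / "out.gff3"
            write_gff3([model], out)
            (model2,) = read_gff3(out, f)
            assert model2.seq == model.seq
            assert model2.exons == model.exons
            assert model2.cds_start == model.cds_start
            assert model2.origin["strand"] == model.origin["strand"]

    def test_generated_corpus_round_trips(self, small_suite, tmp_path):
        out = tmp_path / "corpus"
        small_suite.write(out)
        models = read_gff3(out / "corpus.gff3", out / "corpus.fasta")
        by_id = {m.id: m for m in models}
        for lid, locus in small_suite.loci:
            for gene in locus.genes:
                m = by_id[f"{lid}|{gene.id}"]
                assert m.seq == gene.seq
                assert m.exons == gene.exons
                assert m.cds_start == gene.cds_start
                assert m.skippable_exons == gene.skippable_exons
                assert m.genetic_code == gene.genetic_code


class TestWriteIsoforms:
    def test_empty_report(self, tmp_path):
        report = AnalysisReport(gene_id="g")
        nt, aa = tmp_path / "i.nt.fasta", tmp_path / "i.aa.fasta"
        write_isoforms(report, nt, aa)
        assert nt.read_text() == "" and aa.read_text() == ""

    def test_single_isoform(self, tmp_path):
        report = AnalysisReport(gene_id="g")
        report.isoforms = [Isoform(gene_id="g", event="CONSTITUTIVE", mrna="ATGTAA", cds="ATGTAA", protein="M")]
        nt, aa = tmp_path / "i.nt.fasta", tmp_path / "i.aa.fasta"
        write_isoforms(report, nt, aa)
        assert "ATGTAA" in nt.read_text()
        recs = list(SeqIO.parse(str(aa), "fasta"))
        assert str(recs[0].seq) == "M"

    def test_deterministic_ordering(self, tmp_path):
        report = AnalysisReport(gene_id="g")
        a = Isoform(gene_id="g", event="RETENTION", event_detail={"intron": 0}, mrna="AA", protein="K")
        b = Isoform(gene_id="g", event="ALT3SS_DISTAL", event_detail={"intron": 0}, mrna="CC", protein="P")
        for order in ([a, b], [b, a]):
            report.isoforms = list(order)
            nt, aa = tmp_path / "o.nt.fasta", tmp_path / "o.aa.fasta"
            write_isoforms(report, nt, aa)
            ids = [r.id for r in SeqIO.parse(str(nt), "fasta")]
            assert ids[0].split("|")[1].startswith("ALT3SS_DISTAL")


class TestReportRoundTrip:
    def test_json_round_trip_is_lossless(self, alt3ss_locus):
        from splicedup.pipeline import analyze_gene

        report = analyze_gene(alt3ss_locus.gene, alt3ss_locus.model)
        text = report.to_json()
        back = AnalysisReport.from_json(text)
        assert back.to_json() == text
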