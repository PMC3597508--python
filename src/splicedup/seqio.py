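"""Reading and writing the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO; GFF3 through gffutils (in-memory database).
Everything downstream consumes :class:`~splicedup.models.GeneModel` only —
no other module re-reads files.  Internal coordinates are 0-based half-open
on the sense strand; GFF3 I/O converts to/from the format's 1-based
inclusive convention, and minus-strand genes are reverse-complemented so
``GeneModel.seq`` is always the sense strand.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .models import AnalysisReport, GeneModel, Isoform, ParseError, CoordinateError

_LEGAL_NT = set("ACGTURYSWKMBDHVNacgturyswkmbdhvn")
_LEGAL_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*acdefghiklmnpqrstvwyxbzjuo")


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse nucleotide FASTA into ``(id, sequence)`` pairs, order preserved.

    Sequences are uppercased and U is mapped to T.  A malformed header or an
    illegal character raises :class:`ParseError` naming the offending line.
    """
    _validate_fasta(path, _LEGAL_NT)
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    return records


def read_protein_fasta(path) -> list[tuple[str, str]]:
    """Parse protein FASTA; validation uses the amino-acid alphabet."""
    _validate_fasta(path, _LEGAL_AA)
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def _validate_fasta(path, legal: set) -> None:
    with open(path) as fh:
        lines = fh.readlines()
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if stripped == ">":
                raise ParseError(f"{path}: empty FASTA header at line {lineno}")
            seen_header = True
        else:
            if not seen_header:
                raise ParseError(f"{path}: sequence before any header at line {lineno}")
            bad = set(stripped) - legal
            if bad:
                raise ParseError(
                    f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                )


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path, fasta_path) -> list[GeneModel]:
    """GeneModels from a GFF3 file plus its FASTA.

    One GeneModel per mRNA (ids share the gene id as prefix when several
    mRNAs sit under one gene).  Coordinates become 0-based half-open
    relative to the gene span; minus-strand genes are reverse-complemented.
    A gene without CDS features yields ``cds_start=None`` and is flagged in
    ``source``.
    """
    seqs = dict(read_fasta(fasta_path))
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid not in seqs:
            raise CoordinateError(f"{path}: contig {gene.seqid!r} absent from FASTA")
        contig = seqs[gene.seqid]
        if gene.end > len(contig):
            raise CoordinateError(
                f"{path}: gene {gene.id} ends at {gene.end}, beyond contig length {len(contig)}"
            )
        locus = contig[gene.start - 1 : gene.end]
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start")) or [gene]
        for mrna in mrnas:
            exons = []
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                if ex.start < gene.start or ex.end > gene.end:
                    raise CoordinateError(f"{path}: exon of {mrna.id} outside gene span")
                exons.append((ex.start, ex.end))
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            strand = gene.strand
            seq = locus
            if strand == "-":
                seq = str(Seq(locus).reverse_complement())
                conv = [(gene.end - e, gene.end - s + 1) for s, e in exons]
                exons0 = sorted(conv)
                cds_start = (gene.end - max(c.end for c in cds)) if cds else None
            else:
                exons0 = sorted((s - gene.start, e - gene.start + 1) for s, e in exons)
                cds_start = (min(c.start for c in cds) - gene.start) if cds else None
            attrs = dict(mrna.attributes)
            skippable = [int(x) for x in attrs.get("skippable_exons", [""])[0].split(",") if x != ""] if "skippable_exons" in attrs else []
            code = int(attrs["genetic_code"][0]) if "genetic_code" in attrs else 1
            if mrna is gene:
                mid = gene.attributes.get("ID", [gene.id])[0]
            else:
                # original ID attribute (gffutils may have uniquified .id)
                mid = mrna.attributes.get("ID", [mrna.id])[0]
            models.append(
                GeneModel(
                    id=mid,
                    seq=seq,
                    exons=exons0,
                    cds_start=cds_start,
                    genetic_code=code,
                    source=f"gff3:{os.path.basename(str(path))}" + ("" if cds else ";no_cds"),
                    skippable_exons=skippable,
                    origin={"contig": gene.seqid, "strand": strand, "offset": gene.start - 1, "gene_id": gene.id},
                )
            )
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Write GeneModels back to GFF3 (1-based inclusive), using each model's
    ``origin`` to restore contig, strand and genomic offset when present."""
    lines = ["##gff-version 3"]
    for m in models:
        origin = m.origin or {"contig": m.id, "strand": "+", "offset": 0, "gene_id": m.id}
        contig, strand, off = origin["contig"], origin["strand"], origin["offset"]
        gene_id = origin.get("gene_id", m.id)
        glen = len(m.seq)
        gstart, gend = off + 1, off + glen

        def to_genomic(iv):
            s, e = iv
            if strand == "-":
                return off + glen - e + 1, off + glen - s
            return off + s + 1, off + e

        if gene_id == m.id:
            gene_id = f"{gene_id}.gene"  # keep feature IDs unique for GFF3 parsers
        attrs = [f"ID={m.id}", f"Parent={gene_id}"]
        if m.skippable_exons:
            attrs.append("skippable_exons=" + ",".join(map(str, m.skippable_exons)))
        if m.genetic_code != 1:
            attrs.append(f"genetic_code={m.genetic_code}")
        lines.append(f"{contig}\t.\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gene_id}")
        lines.append(f"{contig}\t.\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t" + ";".join(attrs))
        for iv in m.exons:
            s, e = to_genomic(iv)
            lines.append(f"{contig}\t.\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={m.id}")
        if m.cds_start is not None:
            # record the CDS as running from the start codon through the last exon
            for iv in m.exons:
                if iv[1] <= m.cds_start:
                    continue
                s0 = max(iv[0], m.cds_start)
                s, e = to_genomic((s0, iv[1]))
                lines.append(f"{contig}\t.\tCDS\t{s}\t{e}\t.\t{strand}\t0\tParent={m.id}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_isoforms(report: AnalysisReport, path_nt, path_aa) -> None:
    """Isoform FASTAs (nucleotide message and protein).

    Headers encode gene id, event label and isoform index; ordering is
    deterministic by (event, detail).  Protein records end at the first
    stop by construction.
    """
    isoforms = sorted(report.isoforms, key=lambda i: (i.event, sorted(i.event_detail.items())))
    nt_records, aa_records = [], []
    for idx, iso in enumerate(isoforms):
        rid = f"{report.gene_id}|{iso.label}|{idx}"
        nt_records.append((rid, iso.mrna))
        aa_records.append((rid, iso.protein))
    write_fasta(nt_records, path_nt)
    write_fasta(aa_records, path_aa)


def write_report(report: AnalysisReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(report.to_json())


def read_report(path) -> AnalysisReport:
    with open(path) as fh:
        return AnalysisReport.from_json(fh.read())
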