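"""Isoform enumeration, translation and ORF consequences.

Events mirror the mechanisms fungi use to express two proteins from one
gene: alternative 3' splice sites (proximal acceptor keeps the alternative
exon in the message and yields the long protein), intron retention (the
PTC7 rule: the retained product is functional only when the intron is 3n
nucleotides with no in-frame stop), cassette-exon skipping
(basidiomycete-style), and an internal alternative start codon at the first
methionine of Ski7 motif S1 (Candida-style).  Events are enumerated
one-at-a-time against the constitutive background; combinatorial stacking
of events is deliberately not attempted.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

from .models import (
    ALT3SS_DISTAL,
    ALT3SS_PROXIMAL,
    ALT_START,
    CONSTITUTIVE,
    EXON_SKIP,
    RETENTION,
    GeneModel,
    IntronCandidate,
    Isoform,
    RetentionConsequence,
    SpliceDupError,
)

log = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
WATER_DA = 18.02


def splice(gene: GeneModel, intron: IntronCandidate, acceptor_index: int = 0) -> str:
    """Remove one intron: ``gene.seq`` minus ``[donor_pos, acceptor_pos + 1)``."""
    if not 0 <= acceptor_index < len(intron.acceptors):
        raise SpliceDupError(
            f"acceptor index {acceptor_index} out of range (candidate has {len(intron.acceptors)})"
        )
    start, end = intron.intron_interval(acceptor_index)
    return gene.seq[:start] + gene.seq[end:]


def splice_multi(seq: str, intervals: Iterable[tuple[int, int]]) -> str:
    """Remove several non-overlapping half-open intervals from ``seq``."""
    out = []
    prev = 0
    for start, end in sorted(intervals):
        if start < prev:
            raise SpliceDupError("introns overlap; cannot splice jointly")
        out.append(seq[prev:start])
        prev = end
    out.append(seq[prev:])
    return "".join(out)


def translate(cds: str, genetic_code: int = 1) -> str:
    """Translate to the first stop using NCBI table 1 or 12.

    Table 12 (alternative yeast nuclear) differs from the standard code only
    at CTG (Ser instead of Leu).  An incomplete final codon is ignored with
    a warning; a cds shorter than one codon yields the empty protein.
    """
    if genetic_code not in (1, 12):
        raise SpliceDupError(f"unsupported genetic code {genetic_code}; use 1 or 12")
    if len(cds) < 3:
        log.warning("cds shorter than one codon; empty translation")
        return ""
    if len(cds) % 3:
        log.warning("cds length %d not a multiple of 3; ignoring incomplete final codon", len(cds))
        cds = cds[: len(cds) - len(cds) % 3]
    return str(Seq(cds).translate(table=genetic_code, to_stop=True))


def first_stop_codon(cds: str, genetic_code: int = 1) -> Optional[int]:
    """Codon index of the first in-frame stop, or None."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3] in table.stop_codons:
            return i // 3
    return None


def molecular_weight(protein: str) -> float:
    """Average (not monoisotopic) mass in kDa: residue masses plus one water.

    Raises on the empty string or any non-standard residue.
    """
    if not protein:
        raise SpliceDupError("cannot compute the mass of an empty protein")
    bad = sorted(set(protein) - STANDARD_AA)
    if bad:
        raise SpliceDupError(f"unknown residues in protein: {bad}")
    return _bio_molecular_weight(protein, seq_type="protein", monoisotopic=False) / 1000.0


def _retention_core(
    mrna: str, cds_start: int, intron_start: int, intron_end: int, genetic_code: int = 1
) -> RetentionConsequence:
    """PTC7 retention rule on a transcript that retains one intron.

    ``[intron_start, intron_end)`` is the retained intron on ``mrna``.
    Functional retention requires a 3n intron and no stop codon, in the
    reading frame of the retained transcript, in any codon overlapping the
    intron.
    """
    if intron_start < cds_start:
        raise SpliceDupError("retention outside the CDS is out of scope (intron upstream of start)")
    length = intron_end - intron_start
    frame_preserving = length % 3 == 0
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stop_free = True
    for i in range(cds_start, len(mrna) - 2, 3):
        codon = mrna[i : i + 3]
        overlaps = i < intron_end and i + 3 > intron_start
        if overlaps and codon in table.stop_codons:
            stop_free = False
            break
        if i >= intron_end:
            break
    tail = mrna[cds_start:]
    tail = tail[: len(tail) - len(tail) % 3]
    protein = translate(tail, genetic_code)
    full_codons = len(tail) // 3
    stop_offset = len(protein) if len(protein) < full_codons else None
    return RetentionConsequence(
        frame_preserving=frame_preserving,
        stop_free=stop_free,
        functional_retention=frame_preserving and stop_free,
        stop_offset_aa=stop_offset,
    )


def retention_consequence(
    gene: GeneModel, intron: IntronCandidate, acceptor_index: int = 0
) -> RetentionConsequence:
    """Consequence of retaining ``intron`` (chosen acceptor) in the pre-mRNA."""
    if gene.cds_start is None:
        raise SpliceDupError("retention consequence requires an annotated start codon")
    start, end = intron.intron_interval(acceptor_index)
    return _retention_core(gene.seq, gene.cds_start, start, end, gene.genetic_code)


def find_alt_start(gene: GeneModel, s1_hit_pos_nt: int) -> Optional[Isoform]:
    """Isoform for a Candida-style internal start at motif S1's first residue.

    ``s1_hit_pos_nt`` is the offset, on the unspliced locus, of the codon
    encoding the first residue of motif S1.  If that codon is ATG, an
    ALT_START isoform is emitted whose message begins five nucleotides
    upstream of the start (mirroring the mapped 5' end of the short
    transcript); otherwise ``None`` is returned and the reason logged.
    """
    codon = gene.seq[s1_hit_pos_nt : s1_hit_pos_nt + 3]
    if codon != "ATG":
        log.info("no ALT_START isoform: codon at %d is %s, not ATG", s1_hit_pos_nt, codon)
        return None
    leader = min(5, s1_hit_pos_nt)
    mrna = gene.seq[s1_hit_pos_nt - leader :]
    return _finish_isoform(
        gene,
        Isoform(gene_id=gene.id, event=ALT_START, event_detail={"start_nt": s1_hit_pos_nt}),
        mrna,
        leader,
    )


def _finish_isoform(gene: GeneModel, iso: Isoform, mrna: str, cds_start_mrna: int) -> Isoform:
    cds = mrna[cds_start_mrna:]
    if cds[:3] != "ATG":
        # fall back to the first ATG of the message (determinism rule)
        idx = mrna.find("ATG")
        if idx == -1:
            log.warning("%s %s: no start codon on the message", gene.id, iso.event)
            cds = ""
        else:
            cds = mrna[idx:]
    stop_idx = first_stop_codon(cds, gene.genetic_code) if cds else None
    if stop_idx is not None:
        cds = cds[: 3 * (stop_idx + 1)]  # coding sequence ends at its stop codon
    protein = translate(cds, gene.genetic_code) if cds else ""
    iso.mrna = mrna
    iso.cds = cds
    iso.protein = protein
    iso.stop_codon_offset = stop_idx
    iso.premature_stop = False  # set against the gene's longest isoform later
    iso.length_aa = len(protein)
    iso.mass_kda = molecular_weight(protein) if protein else 0.0
    return iso


def _flag_premature_stops(isoforms: list[Isoform]) -> None:
    """An isoform terminates prematurely when it does not share the
    C-terminus of the gene's longest product (e.g. a stop inside a retained
    intron), rather than merely being shorter."""
    if not isoforms:
        return
    ref = max(isoforms, key=lambda i: i.length_aa).protein
    tail = ref[-10:]
    for iso in isoforms:
        if not iso.protein or iso.protein is ref:
            continue
        iso.premature_stop = iso.stop_codon_offset is not None and not iso.protein.endswith(tail)


def _mrna_cds_start(gene: GeneModel, removed: list[tuple[int, int]]) -> int:
    """Map the genomic cds_start onto the spliced message."""
    pos = gene.cds_start if gene.cds_start is not None else 0
    shift = 0
    for start, end in removed:
        if end <= pos:
            shift += end - start
        elif start <= pos < end:
            # annotated start swallowed by splicing; caller falls back to first ATG
            return -1
    return pos - shift


def _select_nonoverlapping(introns: list[IntronCandidate]) -> list[IntronCandidate]:
    chosen: list[IntronCandidate] = []
    last_end = -1
    for cand in sorted(introns, key=lambda c: c.donor_pos):
        longest_end = max(a for a, _ in cand.acceptors) + 1
        if cand.donor_pos <= last_end:
            log.warning("dropping intron candidate at %d overlapping a previous one", cand.donor_pos)
            continue
        chosen.append(cand)
        last_end = longest_end - 1
    return chosen


def enumerate_isoforms(
    gene: GeneModel,
    introns: list[IntronCandidate],
    events_allowed: Optional[set[str]] = None,
) -> list[Isoform]:
    """Event-labelled isoforms of a locus, one event at a time.

    The spliced background removes every intron at its proximal acceptor.
    Each alternatively spliced intron contributes one isoform per acceptor
    (ALT3SS_PROXIMAL / ALT3SS_DISTAL); with no alternative intron the single
    fully spliced form is CONSTITUTIVE.  Retention isoforms are emitted for
    CDS-overlapping introns whose retention is functional under the PTC7
    rule; cassette exons annotated on the gene yield EXON_SKIP isoforms.
    """
    allowed = events_allowed or {CONSTITUTIVE, ALT3SS_PROXIMAL, ALT3SS_DISTAL, EXON_SKIP, RETENTION}
    introns = _select_nonoverlapping(introns)
    isoforms: list[Isoform] = []

    def build(event: str, detail: dict, acceptor_choice: dict[int, int]) -> Isoform:
        removed = [
            cand.intron_interval(acceptor_choice.get(i, 0)) for i, cand in enumerate(introns)
            if acceptor_choice.get(i, 0) is not None
        ]
        mrna = splice_multi(gene.seq, removed)
        cds_start = _mrna_cds_start(gene, removed)
        iso = Isoform(gene_id=gene.id, event=event, event_detail=detail)
        return _finish_isoform(gene, iso, mrna, max(cds_start, 0))

    alt_introns = [i for i, c in enumerate(introns) if c.alternative]
    if not alt_introns or not (allowed & {ALT3SS_PROXIMAL, ALT3SS_DISTAL}):
        if CONSTITUTIVE in allowed:
            isoforms.append(build(CONSTITUTIVE, {}, {}))
    else:
        for i in alt_introns:
            for j in range(len(introns[i].acceptors)):
                event = ALT3SS_PROXIMAL if j == 0 else ALT3SS_DISTAL
                if event not in allowed:
                    continue
                detail = {"intron": i, "acceptor": j}
                isoforms.append(build(event, detail, {i: j}))

    if RETENTION in allowed:
        for i, cand in enumerate(introns):
            start, _ = cand.intron_interval(0)
            if gene.cds_start is None or start < gene.cds_start:
                continue
            removed = [c.intron_interval(0) for k, c in enumerate(introns) if k != i]
            mrna = splice_multi(gene.seq, removed)
            shift = sum(e - s for s, e in removed if e <= start)
            istart, iend = cand.intron_interval(0)
            cons = _retention_core(
                mrna, _mrna_cds_start(gene, removed), istart - shift, iend - shift, gene.genetic_code
            )
            if cons.functional_retention:
                iso = Isoform(gene_id=gene.id, event=RETENTION, event_detail={"intron": i})
                isoforms.append(_finish_isoform(gene, iso, mrna, _mrna_cds_start(gene, removed)))

    if EXON_SKIP in allowed and gene.skippable_exons and gene.exons:
        removed_all = [c.intron_interval(0) for c in introns]
        base = splice_multi(gene.seq, removed_all)
        # exon intervals on the spliced message
        offsets = []
        pos = 0
        for s, e in gene.exons:
            ln = e - s
            offsets.append((pos, pos + ln))
            pos += ln
        for idx in gene.skippable_exons:
            s, e = offsets[idx]
            mrna = base[:s] + base[e:]
            cds_start = _mrna_cds_start(gene, removed_all)
            skipped_len = e - s
            if cds_start >= e:
                cds_start -= skipped_len
            elif cds_start >= s:
                cds_start = -1
            iso = Isoform(gene_id=gene.id, event=EXON_SKIP, event_detail={"exon": idx})
            isoforms.append(_finish_isoform(gene, iso, mrna, max(cds_start, 0)))

    order = {CONSTITUTIVE: 0, ALT3SS_PROXIMAL: 1, ALT3SS_DISTAL: 2, RETENTION: 3, EXON_SKIP: 4, ALT_START: 5}
    isoforms.sort(key=lambda x: (order.get(x.event, 9), sorted(x.event_detail.items())))
    _flag_premature_stops(isoforms)
    return isoforms
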