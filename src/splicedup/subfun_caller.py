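"""Classify the fate of a duplicated gene pair relative to an alternatively
spliced ancestor.

The ancestor's splice isoforms each provide a subset of the ancestral
functions (on the motif axis, Ski7 and/or Hbs1 function; on the
localization axis, a nuclear-envelope or mitochondrial product).  After
duplication the pair is

* SUBFUNCTIONALIZED when the two paralogs jointly cover the ancestral
  function set, differ from each other, and neither covers it alone —
  the SKI7/HBS1 and T. blattae PTC7a/PTC7b outcome;
* REDUNDANT when each paralog still covers the full ancestral set;
* INCOMPLETE_PARTITION otherwise (functions lost or still shared);
* NOT_COMPARABLE when the ancestor shows only one isoform class.

A DUAL class contributes both the Ski7 and the Hbs1 function, so an
ancestor whose long isoform is DUAL and whose short isoform is HBS1_LIKE
has ancestral function set {SKI7, HBS1}, and paralogs (SKI7_LIKE,
HBS1_LIKE) partition it.  The two axes are never mixed in one verdict.

Mechanism evidence is sequence-level: precise intron loss (the cDNA
recombination signature — the paralog carries the exact spliced exon
junction) and exon loss with a new initiation codon (the paralog starts at
motif S1's methionine with no N-terminal-domain sequence upstream).
"""

from __future__ import annotations

import logging
from typing import Optional

from .models import (
    DUAL,
    HBS1_LIKE,
    MITOCHONDRIAL,
    NEITHER,
    NUCLEAR_ENVELOPE,
    OTHER,
    SKI7_LIKE,
    GeneModel,
    IntronCandidate,
    MotifHit,
    SpliceDupError,
    SubfunReport,
)

log = logging.getLogger(__name__)

SUBFUNCTIONALIZED = "SUBFUNCTIONALIZED"
REDUNDANT = "REDUNDANT"
INCOMPLETE_PARTITION = "INCOMPLETE_PARTITION"
NOT_COMPARABLE = "NOT_COMPARABLE"

MOTIF_AXIS = "MOTIF_COMPLEMENT"
LOCALIZATION_AXIS = "LOCALIZATION"

_FUNCTION_SETS = {
    DUAL: frozenset({"SKI7", "HBS1"}),
    SKI7_LIKE: frozenset({"SKI7"}),
    HBS1_LIKE: frozenset({"HBS1"}),
    NEITHER: frozenset(),
    NUCLEAR_ENVELOPE: frozenset({"NUCLEAR_ENVELOPE"}),
    MITOCHONDRIAL: frozenset({"MITOCHONDRIAL"}),
    OTHER: frozenset(),
}


def _functions(label: str) -> frozenset:
    try:
        return _FUNCTION_SETS[label]
    except KeyError:
        raise SpliceDupError(f"unknown functional class {label!r}") from None


def call_subfunctionalization(
    ancestor_isoform_classes: list[str],
    paralog1_class: str,
    paralog2_class: str,
    axis: str = MOTIF_AXIS,
) -> SubfunReport:
    """Verdict for an (ancestor, paralog pair) triple on one function axis.

    Symmetric under swapping the paralogs.  An ancestor with fewer than two
    distinct isoform classes is NOT_COMPARABLE.
    """
    anc = list(ancestor_isoform_classes)
    if len(set(anc)) < 2:
        return SubfunReport(
            verdict=NOT_COMPARABLE,
            axis=axis,
            ancestor_classes=anc,
            paralog_classes=[paralog1_class, paralog2_class],
            evidence={"reason": "ancestor shows a single isoform class"},
        )
    ancestral = frozenset().union(*(_functions(c) for c in anc))
    f1, f2 = _functions(paralog1_class), _functions(paralog2_class)
    if f1 >= ancestral and f2 >= ancestral:
        verdict = REDUNDANT
    elif (
        (f1 | f2) >= ancestral
        and f1 != f2
        and f1
        and f2
        and not f1 >= ancestral
        and not f2 >= ancestral
    ):
        verdict = SUBFUNCTIONALIZED
    else:
        verdict = INCOMPLETE_PARTITION
    return SubfunReport(
        verdict=verdict,
        axis=axis,
        ancestor_classes=anc,
        paralog_classes=[paralog1_class, paralog2_class],
        evidence={
            "ancestral_functions": sorted(ancestral),
            "paralog_functions": [sorted(f1), sorted(f2)],
        },
    )


def detect_precise_intron_loss(
    ancestor: GeneModel,
    intron: IntronCandidate,
    paralog_seq: str,
    acceptor_index: int = 0,
    k: int = 12,
    max_mismatches: int = 2,
) -> tuple[bool, dict]:
    """Does the paralog carry the exact spliced junction of the ancestor?

    The junction probe concatenates the ancestor's ``k`` exonic nucleotides
    on each side of the chosen acceptor's intron with zero intervening
    bases; the flag is true iff the paralog contains the probe with at most
    ``max_mismatches`` mismatches (absorbing post-duplication divergence).
    """
    start, end = intron.intron_interval(acceptor_index)
    left_avail, right_avail = start, len(ancestor.seq) - end
    kk = min(k, left_avail, right_avail)
    if kk < k:
        log.warning("junction flank shorter than k=%d; shrinking to %d", k, kk)
    if kk == 0:
        return False, {"reason": "no flanking exonic sequence"}
    probe = ancestor.seq[start - kk : start] + ancestor.seq[end : end + kk]
    best_mm, best_pos = len(probe) + 1, None
    for pos in range(len(paralog_seq) - len(probe) + 1):
        mm = sum(1 for a, b in zip(probe, paralog_seq[pos : pos + len(probe)]) if a != b)
        if mm < best_mm:
            best_mm, best_pos = mm, pos
            if mm == 0:
                break
    flag = best_pos is not None and best_mm <= max_mismatches
    return flag, {
        "junction_probe": probe,
        "k": kk,
        "best_match_pos": best_pos,
        "mismatches": best_mm if best_pos is not None else None,
        "max_mismatches": max_mismatches,
    }


def detect_exon_loss_new_start(
    ancestor_long_hits: list[MotifHit],
    paralog: GeneModel,
    motif_models: dict,
    d: int = 3,
) -> tuple[Optional[bool], dict]:
    """Did the paralog lose exon 1 and gain a new start codon at motif S1?

    True iff the paralog's start codon lies within ``d`` residues of its S1
    motif (S1 at the extreme N-terminus, as in post-WGD Ski7) AND no NTD
    motif is detectable in any reading frame of the paralog sequence
    upstream of the start codon (no residual exon-1 homology; the NTD motif
    is the exon-1 diagnostic, so no aligner is needed).  Returns
    ``(None, ...)`` when the ancestor's long isoform lacks S1.
    """
    from .isoform_engine import translate
    from .motif_classifier import scan_motifs

    if not any(h.motif_id == "S1" for h in ancestor_long_hits):
        return None, {"reason": "ancestor long isoform lacks motif S1; not comparable"}
    cds_start = paralog.cds_start if paralog.cds_start is not None else max(paralog.seq.find("ATG"), 0)
    protein = translate(paralog.seq[cds_start:], paralog.genetic_code)
    if not protein:
        return False, {"reason": "paralog has no translatable CDS"}
    s1 = [h for h in scan_motifs(protein, motif_models) if h.motif_id == "S1"]
    if not s1:
        return False, {"reason": "paralog protein lacks motif S1"}
    s1_start = min(h.start for h in s1)
    start_near_s1 = s1_start <= d
    upstream = paralog.seq[:cds_start]
    upstream_ntd = False
    ntd_model = {k: v for k, v in motif_models.items() if k == "NTD"}
    for frame in range(3):
        frame_prot = translate_through(upstream[frame:], paralog.genetic_code)
        if len(frame_prot) >= len(motif_models["NTD"]) and any(
            h.motif_id == "NTD" for h in scan_motifs(frame_prot, ntd_model)
        ):
            upstream_ntd = True
            break
    flag = start_near_s1 and not upstream_ntd
    return flag, {
        "s1_offset_aa": s1_start,
        "d": d,
        "start_near_s1": start_near_s1,
        "upstream_ntd_hit": upstream_ntd,
    }


def translate_through(nt: str, genetic_code: int = 1) -> str:
    """Translate without stopping; stops become ``*`` (for homology scans)."""
    from Bio.Seq import Seq

    nt = nt[: len(nt) - len(nt) % 3]
    if not nt:
        return ""
    return str(Seq(nt).translate(table=genetic_code))
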