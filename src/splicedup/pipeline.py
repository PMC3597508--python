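"""End-to-end orchestration: gene -> introns -> isoforms -> classes/calls.

This is the glue the CLI subcommands and the synthetic-suite evaluation
share.  The alternative-start search follows the logic used for the CTG
clade: an internal initiation codon at motif S1 is only a credible route
to a Ski7-like product when no spliced isoform already encodes S1 (in
species with a proximal 3' splice site the long splice form provides S1,
and no internal-start message has been observed).  ``alt_start=True``
forces the search regardless; ``alt_start=False`` disables it.
"""

from __future__ import annotations

from typing import Optional

from . import __version__
from .isoform_engine import enumerate_isoforms, find_alt_start
from .localization import localize
from .models import AnalysisReport, GeneModel, SubfunReport
from .motif_classifier import classify_isoform, load_motif_models, scan_motifs
from .splice_signals import SpliceSignalModel, enumerate_introns, load_default_model
from .subfun_caller import (
    LOCALIZATION_AXIS,
    MOTIF_AXIS,
    call_subfunctionalization,
    detect_exon_loss_new_start,
    detect_precise_intron_loss,
    translate_through,
)


def _genomic_s1_position(gene: GeneModel, motif_models) -> Optional[int]:
    """Nucleotide offset of an ATG-initiated S1 motif in any genomic frame."""
    s1 = motif_models.get("S1")
    if s1 is None:
        return None
    best = None
    for frame in range(3):
        prot = translate_through(gene.seq[frame:], gene.genetic_code)
        if len(prot) < len(s1):
            continue
        for hit in scan_motifs(prot, {"S1": s1}):
            nt = frame + 3 * hit.start
            if gene.seq[nt : nt + 3] == "ATG" and (best is None or nt < best):
                best = nt
    return best


def analyze_gene(
    gene: GeneModel,
    model: Optional[SpliceSignalModel] = None,
    motif_models=None,
    alt_start: Optional[bool] = None,
    events_allowed=None,
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Full single-gene analysis: splice scan, isoforms, motifs, localization."""
    model = model or load_default_model()
    motif_models = motif_models or load_motif_models()
    introns = enumerate_introns(gene, model)
    isoforms = enumerate_isoforms(gene, introns, events_allowed)

    def s1_present(iso) -> bool:
        return iso.protein and any(
            h.motif_id == "S1" for h in scan_motifs(iso.protein, motif_models)
        )

    want_alt = alt_start is True or (alt_start is None and not any(map(s1_present, isoforms)))
    if want_alt and alt_start is not False:
        pos = _genomic_s1_position(gene, motif_models)
        if pos is not None:
            iso = find_alt_start(gene, pos)
            if iso is not None:
                isoforms.append(iso)

    report = AnalysisReport(
        gene_id=gene.id,
        provenance={
            "tool": "splicedup",
            "version": __version__,
            "splice_model": model.to_config(),
            "seed": seed,
            "localization_method": "heuristic stand-in",
        },
    )
    report.isoforms = isoforms
    for idx, iso in enumerate(isoforms):
        key = f"{iso.label}|{idx}"
        if iso.protein:
            hits = scan_motifs(iso.protein, motif_models)
            report.motif_hits[key] = hits
            report.classifications[key] = classify_isoform(hits)
            report.localizations[key] = localize(iso.protein)
    return report


def analyze_pair(
    ancestor: GeneModel,
    paralog1: GeneModel,
    paralog2: GeneModel,
    axis: str = MOTIF_AXIS,
    model: Optional[SpliceSignalModel] = None,
    motif_models=None,
) -> SubfunReport:
    """Subfunctionalization analysis of a duplicated pair against an
    alternatively spliced ancestor, on one function axis."""
    model = model or load_default_model()
    motif_models = motif_models or load_motif_models()
    anc_report = analyze_gene(ancestor, model, motif_models)
    reports = {g.id: analyze_gene(g, model, motif_models) for g in (paralog1, paralog2)}

    def classes_of(report, axis):
        out = []
        for idx, iso in enumerate(report.isoforms):
            key = f"{iso.label}|{idx}"
            if axis == MOTIF_AXIS and key in report.classifications:
                out.append(report.classifications[key].label)
            elif axis == LOCALIZATION_AXIS and key in report.localizations:
                out.append(report.localizations[key].label)
        return out

    anc_classes = classes_of(anc_report, axis)
    p_classes = {g.id: classes_of(reports[g.id], axis) for g in (paralog1, paralog2)}
    c1 = p_classes[paralog1.id][0] if p_classes[paralog1.id] else "NEITHER"
    c2 = p_classes[paralog2.id][0] if p_classes[paralog2.id] else "NEITHER"
    verdict = call_subfunctionalization(anc_classes, c1, c2, axis=axis)

    anc_introns = enumerate_introns(ancestor, model)
    mechanisms = {}
    target = None
    for cand in anc_introns:
        if cand.alternative or target is None:
            target = cand
    long_hits = []
    for idx, iso in enumerate(anc_report.isoforms):
        key = f"{iso.label}|{idx}"
        hits = anc_report.motif_hits.get(key, [])
        if any(h.motif_id == "S1" for h in hits):
            long_hits = hits
            break
    for g in (paralog1, paralog2):
        mech = {"precise_intron_loss": False, "exon_loss_new_start": None}
        if target is not None:
            flag, ev = detect_precise_intron_loss(
                ancestor, target, g.seq, acceptor_index=len(target.acceptors) - 1
            )
            mech["precise_intron_loss"] = flag
            mech["precise_intron_loss_evidence"] = ev
        flag2, ev2 = detect_exon_loss_new_start(long_hits, g, motif_models)
        mech["exon_loss_new_start"] = flag2
        mech["exon_loss_evidence"] = ev2
        mechanisms[g.id] = mech

    verdict.mechanisms = mechanisms
    verdict.evidence.update(
        {
            "ancestor_isoforms": [iso.label for iso in anc_report.isoforms],
            "paralog_isoforms": {gid: [i.label for i in r.isoforms] for gid, r in reports.items()},
        }
    )
    return verdict


# --------------------------------------------------------------------------
# ground-truth evaluation of generated loci (used by the acceptance suite)
# --------------------------------------------------------------------------


def evaluate_locus(locus) -> dict:
    """Run the pipeline on a generated locus and compare with its truth."""
    from .subfun_caller import LOCALIZATION_AXIS

    truth = locus.truth
    result = {"kind": truth.kind, "checks": {}}
    checks = result["checks"]
    if truth.expected_verdict is None:
        gene = locus.genes[0]
        report = analyze_gene(gene, locus.model)
        got_events = sorted(iso.event for iso in report.isoforms)
        want_events = sorted(truth.expected_isoforms[gene.id])
        checks["isoform_set"] = got_events == want_events
        by_event = {}
        for idx, iso in enumerate(report.isoforms):
            by_event.setdefault(iso.event, f"{iso.label}|{idx}")
        if truth.expected_classes.get(gene.id):
            ok = True
            for event, want in truth.expected_classes[gene.id].items():
                key = by_event.get(event)
                got = report.classifications.get(key)
                ok &= got is not None and got.label == want
            checks["classes"] = ok
        if truth.expected_localizations.get(gene.id):
            ok = True
            for event, want in truth.expected_localizations[gene.id].items():
                key = by_event.get(event)
                got = report.localizations.get(key)
                ok &= got is not None and got.label == want
            checks["localizations"] = ok
    else:
        anc, p1, p2 = locus.genes
        verdict = analyze_pair(anc, p1, p2, axis=truth.axis, model=locus.model)
        checks["verdict"] = verdict.verdict == truth.expected_verdict
        mech_ok = True
        for gid, want in truth.expected_mechanisms.items():
            got = verdict.mechanisms.get(gid, {})
            for flag_name, want_val in want.items():
                mech_ok &= got.get(flag_name) == want_val
        checks["mechanisms"] = mech_ok
    result["ok"] = all(checks.values())
    return result


def evaluate_suite(corpus) -> dict:
    """Per-locus evaluation plus summary recovery rates for a corpus."""
    rows = []
    for lid, locus in corpus.loci:
        res = evaluate_locus(locus)
        res["locus_id"] = lid
        rows.append(res)
    n = len(rows)
    ok = sum(r["ok"] for r in rows)
    pair_rows = [r for r in rows if r["kind"] == "POST_WGD_PAIR"]
    mech_ok = sum(r["checks"].get("mechanisms", False) for r in pair_rows)
    return {
        "rows": rows,
        "n_loci": n,
        "n_recovered": ok,
        "recovery_rate": ok / n if n else 0.0,
        "n_pairs": len(pair_rows),
        "mechanism_recovery_rate": (mech_ok / len(pair_rows)) if pair_rows else None,
    }
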