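"""N-terminal sorting-signal heuristics and PTC7-style localization calls.

Two transparent heuristics stand in for external topology/sorting servers
(they are labelled "heuristic stand-in" in provenance and make no claim of
agreement with any server):

* a sliding-window Kyte-Doolittle hydropathy scan for a single predicted
  transmembrane helix near the N-terminus — the signal that anchors the
  intron-retained Ptc7 isoform in the nuclear envelope; and
* a composition score for a mitochondrial targeting presequence (MTS):
  arginine/lysine enrichment raises it, aspartate/glutamate lowers it, and
  serine/leucine/alanine enrichment — typical of presequences — rewards it.

The localization call is a fixed precedence: an N-terminal TM wins over an
MTS, mirroring the biology in which the retained-intron isoform carries
the TM and goes to the nuclear envelope even though everything downstream
is shared with the mitochondrial isoform.
"""

from __future__ import annotations

import logging

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .models import MITOCHONDRIAL, NUCLEAR_ENVELOPE, OTHER, LocalizationCall, TMPrediction

log = logging.getLogger(__name__)

# mts_score component weights (config-overridable via keyword arguments)
MTS_WEIGHTS = {"positive": 2.0, "negative": 2.0, "sla": 0.5}


def hydropathy_tm(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    n_terminal_span: int = 60,
) -> TMPrediction:
    """Predict transmembrane helices by windowed mean Kyte-Doolittle hydropathy.

    Maximal runs of windows whose mean is >= ``threshold`` are merged into
    helices ``(start, end, mean hydropathy)``; ``n_terminal_tm`` is true iff
    a helix starts within the first ``n_terminal_span`` residues.  Proteins
    shorter than one window yield no prediction (with a warning).
    """
    if len(protein) < window:
        log.warning("protein of length %d shorter than window %d; no TM prediction", len(protein), window)
        return TMPrediction(window_scores=[], helices=[], n_terminal_tm=False)
    values = [KYTE_DOOLITTLE.get(c, 0.0) for c in protein]
    scores = []
    acc = sum(values[:window])
    scores.append(acc / window)
    for i in range(1, len(protein) - window + 1):
        acc += values[i + window - 1] - values[i - 1]
        scores.append(acc / window)

    helices = []
    run_start = None
    for i, s in enumerate(scores + [float("-inf")]):
        if s >= threshold and run_start is None:
            run_start = i
        elif s < threshold and run_start is not None:
            start, end = run_start, i - 1 + window
            mean = sum(values[start:end]) / (end - start)
            helices.append((start, end, mean))
            run_start = None
    n_term = any(start < n_terminal_span for start, _, _ in helices)
    return TMPrediction(window_scores=scores, helices=helices, n_terminal_tm=n_term)


def mts_score(protein: str, span: int = 30, weights: dict | None = None) -> float:
    """Mitochondrial-targeting-presequence score in [0, 1] over the first ``span`` residues.

    ``(w_pos * #RK - w_neg * #DE + w_sla * #SLA) / span``, clipped to [0, 1]:
    monotone increasing in R/K and S/L/A counts, decreasing in D/E.
    """
    w = dict(MTS_WEIGHTS)
    if weights:
        w.update(weights)
    head = protein[:span]
    if not head:
        return 0.0
    pos = sum(head.count(c) for c in "RK")
    neg = sum(head.count(c) for c in "DE")
    sla = sum(head.count(c) for c in "SLA")
    raw = (w["positive"] * pos - w["negative"] * neg + w["sla"] * sla) / span
    return min(1.0, max(0.0, raw))


def localize(
    protein: str,
    mts_cutoff: float = 0.5,
    window: int = 19,
    tm_threshold: float = 1.6,
    n_terminal_span: int = 60,
    mts_span: int = 30,
) -> LocalizationCall:
    """PTC7-style call: NUCLEAR_ENVELOPE on an N-terminal TM, else
    MITOCHONDRIAL on a sufficient MTS score, else OTHER.

    The TM-over-MTS precedence is total and deterministic.
    """
    tm = hydropathy_tm(protein, window=window, threshold=tm_threshold, n_terminal_span=n_terminal_span)
    mts = mts_score(protein, span=mts_span)
    evidence = {
        "n_terminal_tm": tm.n_terminal_tm,
        "helices": [(s, e, round(m, 3)) for s, e, m in tm.helices],
        "mts_score": round(mts, 4),
        "mts_cutoff": mts_cutoff,
        "method": "heuristic stand-in (windowed hydropathy + composition score)",
    }
    if tm.n_terminal_tm:
        label = NUCLEAR_ENVELOPE
    elif mts >= mts_cutoff:
        label = MITOCHONDRIAL
    else:
        label = OTHER
    return LocalizationCall(label=label, evidence=evidence)
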