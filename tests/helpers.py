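"""Independent oracles for the test suite.

These re-derive expected results from first principles (exhaustive
enumeration, literal lookup tables, naive window arithmetic) and stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import math

# The standard genetic code, written out (independent of any library).
STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def naive_pwm_score(probs, window: str) -> float | None:
    """Log-odds of a window against uniform 0.25, from a probability matrix."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for i, c in enumerate(window):
        if c not in idx:
            return None
        total += math.log2(probs[i][idx[c]] / 0.25)
    return total


def naive_scan(seq: str, probs, threshold: float):
    """Brute-force rescan of every window; the oracle for scan_signal."""
    w = len(probs)
    hits = []
    for pos in range(len(seq) - w + 1):
        s = naive_pwm_score(probs, seq[pos : pos + w])
        if s is not None and s >= threshold:
            hits.append((pos, s))
    return hits


def brute_force_introns(seq: str, model):
    """Exhaustive GT..AG enumeration under the model's constraints.

    Re-derives candidate introns by scanning every GT start and AG end
    directly, with its own PWM arithmetic, then applies the same branch
    tie-break (best score, leftmost) as the published procedure describes.
    Returns a list of (donor, branch, tuple(acceptors)).
    """
    dprobs = model.donor_pwm.probs.tolist()
    bprobs = model.branch_pwm.probs.tolist()
    aprobs = model.acceptor_pwm.probs.tolist()
    thr = model.thresholds
    wmin, wmax = model.branch_to_acceptor_window
    donors = []
    for d in range(len(seq) - len(dprobs) + 1):
        if seq[d : d + 2] != "GT":
            continue
        s = naive_pwm_score(dprobs, seq[d : d + len(dprobs)])
        if s is not None and s >= thr["donor"]:
            donors.append(d)
    branches = []
    for b in range(len(seq) - len(bprobs) + 1):
        s = naive_pwm_score(bprobs, seq[b : b + len(bprobs)])
        if s is not None and s >= thr["branch"]:
            branches.append((b, s))
    acceptors = []
    for p in range(len(seq) - len(aprobs) + 1):
        a = p + len(aprobs) - 1
        if seq[a - 1 : a + 1] != "AG":
            continue
        s = naive_pwm_score(aprobs, seq[p : p + len(aprobs)])
        if s is not None and s >= thr["acceptor"]:
            acceptors.append(a)
    out = []
    for d in donors:
        best = None
        for b, bs in sorted(branches, key=lambda t: (-t[1], t[0])):
            if b < d + len(dprobs) or b + len(bprobs) > d + model.max_intron_len:
                continue
            accs = [
                a
                for a in acceptors
                if b + len(bprobs) <= a - 1
                and wmin <= a - b <= wmax
                and model.min_intron_len <= a + 1 - d <= model.max_intron_len
            ]
            if accs:
                best = (b, tuple(sorted(accs)))
                break
        if best is not None:
            out.append((d, best[0], best[1]))
    return sorted(out)


def naive_retention(intron: str, host_upstream_codons: int = 0) -> bool:
    """PTC7 rule, phase 0: 3n intron with no stop codon in frame."""
    if len(intron) % 3 != 0:
        return False
    for i in range(0, len(intron) - 2, 3):
        if STANDARD_CODE[intron[i : i + 3]] == "*":
            return False
    return True
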