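"""Fungal splice-signal models and candidate-intron enumeration.

Budding-yeast-style introns carry three short signals: a 5' donor site
(consensus GUAUGU), a branch-point heptamer (UACUAAC) and a 3' acceptor
(YAG).  Each signal is modelled as a position weight matrix (PWM) built
from aligned example sites; scores are log-odds (base 2) against a uniform
0.25 background.  An intron candidate is a donor plus its best compatible
branch point plus *all* acceptors that satisfy the geometric constraints —
a candidate with two or more acceptors is an alternative-3'-splice-site
intron of the kind seen in ascomycete SKI7/HBS1 genes, where the proximal
acceptor yields the long (Ski7-like) protein and the distal acceptor the
short (Hbs1-like) one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .models import GeneModel, IntronCandidate, SpliceDupError

NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NT)}
BACKGROUND = 0.25


class PWM:
    """Position weight matrix over A/C/G/T with log-odds scoring.

    Columns are probability distributions (they sum to 1); scoring uses
    log2(p / 0.25).  Windows containing ambiguity codes score ``None``
    (conservative: an ambiguous signal is a non-match).
    """

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM expects an (L, 4) probability matrix")
        if not np.allclose(probs.sum(axis=1), 1.0):
            raise ValueError("PWM columns must sum to 1")
        self.probs = probs
        with np.errstate(divide="ignore"):  # zero-probability letters score -inf
            self.logodds = np.log2(probs / BACKGROUND)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(NT[i] for i in self.probs.argmax(axis=1))

    def score(self, window: str) -> float | None:
        if len(window) != len(self):
            raise ValueError("window length does not match PWM length")
        total = 0.0
        for i, c in enumerate(window):
            j = _NT_INDEX.get(c)
            if j is None:
                return None
            total += self.logodds[i, j]
        return total

    def to_lists(self) -> list[list[float]]:
        return self.probs.tolist()


def build_pwm(aligned_sites: list[str], pseudocount: float = 0.5) -> PWM:
    """Build a PWM from equal-length aligned sites.

    Per column, each letter's count plus ``pseudocount`` is normalised to a
    probability.  Raises on zero sites or unequal lengths.
    """
    if not aligned_sites:
        raise SpliceDupError("build_pwm requires at least one site")
    length = len(aligned_sites[0])
    if any(len(s) != length for s in aligned_sites):
        raise SpliceDupError("aligned sites must all have the same length")
    counts = np.full((length, 4), float(pseudocount))
    for site in aligned_sites:
        for i, c in enumerate(site.upper().replace("U", "T")):
            if c not in _NT_INDEX:
                raise SpliceDupError(f"illegal letter {c!r} in aligned site {site!r}")
            counts[i, _NT_INDEX[c]] += 1.0
    return PWM(counts / counts.sum(axis=1, keepdims=True))


_NT_CODE = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(NT):
    _NT_CODE[ord(_c)] = _i


def scan_signal(seq: str, pwm: PWM, threshold: float) -> list[tuple[int, float]]:
    """All windows of ``seq`` scoring >= threshold, sorted by position.

    Windows containing ambiguity codes are skipped.
    """
    w = len(pwm)
    n = len(seq)
    if n < w:
        return []
    codes = _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = n - w + 1
    total = np.zeros(m)
    ok = np.ones(m, dtype=bool)
    for k in range(w):
        c = codes[k : k + m]
        ok &= c >= 0
        total += pwm.logodds[k][np.where(c >= 0, c, 0)]
    idx = np.nonzero(ok & (total >= threshold))[0]
    return [(int(i), float(total[i])) for i in idx]


# canonical budding-yeast training sites; the acceptor is YAG.  These are
# config-overridable stand-ins: published gene figures give logos, not
# matrices (flagged as such in provenance output).
DEFAULT_DONOR_SITES = ["GTATGT", "GTAAGT"]
DEFAULT_BRANCH_SITES = ["TACTAAC"]
DEFAULT_ACCEPTOR_SITES = ["TAG", "CAG"]


@dataclass
class SpliceSignalModel:
    """PWMs plus geometry and score thresholds for intron search."""

    donor_pwm: PWM
    branch_pwm: PWM
    acceptor_pwm: PWM
    min_intron_len: int = 40
    max_intron_len: int = 1000
    branch_to_acceptor_window: tuple[int, int] = (10, 200)
    thresholds: dict = field(default_factory=dict)  # absolute log-odds per signal
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.min_intron_len >= self.max_intron_len:
            raise SpliceDupError("min_intron_len must be < max_intron_len")
        if self.branch_to_acceptor_window[0] < 1:
            raise SpliceDupError("branch_to_acceptor window min must be >= 1")

    @classmethod
    def from_sites(
        cls,
        donor_sites=None,
        branch_sites=None,
        acceptor_sites=None,
        pseudocount: float = 0.5,
        threshold_fraction: float = 0.6,
        **geometry,
    ) -> "SpliceSignalModel":
        donor = build_pwm(donor_sites or DEFAULT_DONOR_SITES, pseudocount)
        branch = build_pwm(branch_sites or DEFAULT_BRANCH_SITES, pseudocount)
        acceptor = build_pwm(acceptor_sites or DEFAULT_ACCEPTOR_SITES, pseudocount)
        thresholds = {
            "donor": threshold_fraction * donor.max_score,
            "branch": threshold_fraction * branch.max_score,
            "acceptor": threshold_fraction * acceptor.max_score,
        }
        prov = {
            "pseudocount": pseudocount,
            "threshold_fraction": threshold_fraction,
            "training_sites": "default-consensus stand-in"
            if donor_sites is None
            else "user-supplied",
        }
        return cls(donor, branch, acceptor, thresholds=thresholds, provenance=prov, **geometry)

    @classmethod
    def default(cls) -> "SpliceSignalModel":
        return cls.from_sites()

    # -- config (de)serialization -------------------------------------------------
    def to_config(self) -> dict:
        return {
            "donor_pwm": self.donor_pwm.to_lists(),
            "branch_pwm": self.branch_pwm.to_lists(),
            "acceptor_pwm": self.acceptor_pwm.to_lists(),
            "min_intron_len": self.min_intron_len,
            "max_intron_len": self.max_intron_len,
            "branch_to_acceptor_window": list(self.branch_to_acceptor_window),
            "thresholds": self.thresholds,
            "provenance": self.provenance,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "SpliceSignalModel":
        try:
            if "donor_pwm" in cfg:
                donor = PWM(np.array(cfg["donor_pwm"]))
                branch = PWM(np.array(cfg["branch_pwm"]))
                acceptor = PWM(np.array(cfg["acceptor_pwm"]))
                model = cls(
                    donor,
                    branch,
                    acceptor,
                    min_intron_len=int(cfg.get("min_intron_len", 40)),
                    max_intron_len=int(cfg.get("max_intron_len", 1000)),
                    branch_to_acceptor_window=tuple(
                        cfg.get("branch_to_acceptor_window", (10, 200))
                    ),
                    thresholds=dict(cfg["thresholds"]),
                    provenance=dict(cfg.get("provenance", {})),
                )
                return model
            return cls.from_sites(
                donor_sites=cfg.get("donor_sites"),
                branch_sites=cfg.get("branch_sites"),
                acceptor_sites=cfg.get("acceptor_sites"),
                pseudocount=cfg.get("pseudocount", 0.5),
                threshold_fraction=cfg.get("threshold_fraction", 0.6),
                min_intron_len=cfg.get("min_intron_len", 40),
                max_intron_len=cfg.get("max_intron_len", 1000),
                branch_to_acceptor_window=tuple(cfg.get("branch_to_acceptor_window", (10, 200))),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SpliceDupError(f"bad splice model config: {exc}") from exc

    @classmethod
    def from_config_file(cls, path) -> "SpliceSignalModel":
        with open(path) as fh:
            return cls.from_config(json.load(fh))


def load_default_model() -> SpliceSignalModel:
    """The packaged default splice model (canonical budding-yeast signals)."""
    cfg = json.loads(resources.files("splicedup.data").joinpath("splice_model.json").read_text())
    return SpliceSignalModel.from_config(cfg)


def enumerate_introns(gene: GeneModel, model: SpliceSignalModel) -> list[IntronCandidate]:
    """All candidate introns of a locus, including alternative 3' splice sites.

    For each donor window passing the donor threshold (and literally starting
    GT), the branch point with the highest PWM score that admits at least one
    acceptor is kept (leftmost on ties), and *all* acceptors compatible with
    the geometry — intron length within bounds, acceptor within the
    branch-to-acceptor window, intron literally ending AG — are collected,
    sorted proximal to distal.  Overlapping donors are all reported;
    resolution is left to isoform assembly.
    """
    seq = gene.seq
    wmin, wmax = model.branch_to_acceptor_window
    donors = [
        (pos, s)
        for pos, s in scan_signal(seq, model.donor_pwm, model.thresholds["donor"])
        if seq[pos : pos + 2] == "GT"
    ]
    branches = scan_signal(seq, model.branch_pwm, model.thresholds["branch"])
    acceptor_hits = scan_signal(seq, model.acceptor_pwm, model.thresholds["acceptor"])
    # acceptor_pos = offset of the intron's final G; the intron must literally end AG
    acceptors = [
        (pos + len(model.acceptor_pwm) - 1, s)
        for pos, s in acceptor_hits
        if seq[pos + len(model.acceptor_pwm) - 2 : pos + len(model.acceptor_pwm)] == "AG"
    ]

    candidates = []
    blen = len(model.branch_pwm)
    for d, dscore in donors:
        best: tuple[int, float, list] | None = None
        # branch points after the donor hexamer, ranked by (-score, position)
        local = [
            (b, bs)
            for b, bs in branches
            if b >= d + len(model.donor_pwm) and b + blen <= d + model.max_intron_len
        ]
        for b, bs in sorted(local, key=lambda t: (-t[1], t[0])):
            compatible = [
                (a, ascore)
                for a, ascore in acceptors
                if b + blen <= a - 1
                and wmin <= a - b <= wmax
                and model.min_intron_len <= a + 1 - d <= model.max_intron_len
            ]
            if compatible:
                best = (b, bs, sorted(compatible))
                break
        if best is not None:
            b, bs, accs = best
            candidates.append(
                IntronCandidate(
                    donor_pos=d,
                    branch_pos=b,
                    acceptors=accs,
                    donor_score=dscore,
                    branch_score=bs,
                )
            )
    candidates.sort(key=lambda c: c.donor_pos)
    return candidates


def sites_to_bed(gene: GeneModel, candidates: list[IntronCandidate]) -> str:
    """BED (0-based half-open) lines for all candidate splice sites."""
    lines = []
    for idx, c in enumerate(candidates):
        lines.append(
            f"{gene.id}\t{c.donor_pos}\t{c.donor_pos + 6}\tdonor.{idx}\t{c.donor_score:.3f}\t+"
        )
        lines.append(
            f"{gene.id}\t{c.branch_pos}\t{c.branch_pos + 7}\tbranch.{idx}\t{c.branch_score:.3f}\t+"
        )
        for j, (a, s) in enumerate(c.acceptors):
            lines.append(f"{gene.id}\t{a - 2}\t{a + 1}\tacceptor.{idx}.{j}\t{s:.3f}\t+")
    return "\n".join(lines) + ("\n" if lines else "")
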