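"""Synthetic fungal gene loci with planted architectures and ground truth.

Every pipeline stage is testable without downloads: the generator emits
loci that emulate the gene architectures observed across fungi —

* ``ALT3SS`` — a pre-WGD budding-yeast-like gene: one intron whose two 3'
  splice sites flank an alternative exon carrying the Ski7 motifs S1 and
  S2, sized so the two predicted proteins come out near 70 and 96 kDa;
* ``MULTI_INTRON_ALT3SS`` — a multi-intron ascomycete gene (seven introns
  by default, four for an Aspergillus-like locus) whose second intron
  carries the two alternative 3' splice sites;
* ``ALT_TSS`` — a CTG-clade-like gene (genetic code 12) with a single
  distal 3' splice site and an internal ATG at motif S1 that starts the
  Ski7-like message;
* ``EXON_SKIP`` — a basidiomycete-like gene whose cassette exon carries
  S1/S2;
* ``RETENTION_PAIR`` — a PTC7-like gene: a frame-preserving, stop-free
  intron encodes an N-terminal transmembrane helix, the spliced product
  carries a mitochondrial presequence (a non-functional variant plants a
  103-nt intron with an in-frame stop 20 codons into the ORF and a single
  internal ATG eight codons upstream of the normal stop);
* ``POST_WGD_PAIR`` — an alternatively spliced ancestor plus two derived
  paralogs: one with the intron precisely excised (Hbs1-like), one that
  lost exon 1 and starts at S1's methionine with the catalytic G3 His
  substituted (Ski7-like); a LOCALIZATION-axis variant derives a
  PTC7a/PTC7b-like pair instead.

Planted signals are drawn from the splice-signal PWMs at a requested
signal strength (1.0 = consensus).  Background is i.i.d. at a configurable
GC for non-coding segments and a polar-biased residue composition for
coding segments (reverse-translated with uniformly random synonymous
codons).  After assembly each locus is *sanitized*: any unplanted
donor/branch/acceptor combination passing the default thresholds is
removed by minimal synonymous or non-coding edits (resampling the whole
locus when impossible), so false-positive measurements downstream are
meaningful.  Paralog divergence applies per-site substitutions that never
touch splice signals, motif codons, the excision junction read by the
mechanism detector, start codons, or introduce in-frame stops.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from Bio.Data import CodonTable
from Bio.Data.IUPACData import protein_weights

from . import subfun_caller
from .models import (
    ALT3SS_DISTAL,
    ALT3SS_PROXIMAL,
    ALT_START,
    CONSTITUTIVE,
    DUAL,
    EXON_SKIP,
    HBS1_LIKE,
    MITOCHONDRIAL,
    NUCLEAR_ENVELOPE,
    RETENTION,
    SKI7_LIKE,
    GeneModel,
    SpliceDupError,
)
from .motif_classifier import load_motif_models
from .splice_signals import PWM, SpliceSignalModel, enumerate_introns

WATER = 18.0153

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
# polar-biased background composition (fractions); hydrophobics are kept rare
# so unplanted transmembrane stretches do not arise by chance
AA_WEIGHTS = {
    "A": 0.09, "C": 0.01, "D": 0.06, "E": 0.07, "F": 0.02, "G": 0.08,
    "H": 0.03, "I": 0.03, "K": 0.08, "L": 0.05, "M": 0.02, "N": 0.05,
    "P": 0.05, "Q": 0.05, "R": 0.06, "S": 0.09, "T": 0.08, "V": 0.04,
    "W": 0.01, "Y": 0.03,
}

MEAN_RESIDUE_MASS = sum(w * (protein_weights[a] - WATER) for a, w in AA_WEIGHTS.items())

# the two predicted protein masses of the L. kluyveri-like ALT3SS locus (Da);
# the generator derives its exon sizes from these at run time
SHORT_ISOFORM_MASS = 70000.0
LONG_ISOFORM_MASS = 96000.0


def _codon_tables() -> dict[int, dict[str, list[str]]]:
    out = {}
    for tid in (1, 12):
        table = CodonTable.unambiguous_dna_by_id[tid]
        by_aa: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            by_aa.setdefault(aa, []).append(codon)
        out[tid] = {aa: sorted(cs) for aa, cs in by_aa.items()}
    return out


CODONS = _codon_tables()
STOPS = {tid: set(CodonTable.unambiguous_dna_by_id[tid].stop_codons) for tid in (1, 12)}


# --------------------------------------------------------------------------
# locus assembly: parts with frame bookkeeping so sanitization and divergence
# can make synonymous edits and avoid creating stops
# --------------------------------------------------------------------------


@dataclass
class _Part:
    name: str
    kind: str  # fixed | nc | codon
    protect: bool = False
    nt: list = field(default_factory=list)  # fixed/nc
    aa: list = field(default_factory=list)  # codon
    codons: list = field(default_factory=list)
    locked: set = field(default_factory=set)  # divergence-proof codons (aa preserved)
    nt_locked: set = field(default_factory=set)  # nucleotide-exact codons (no edits at all)
    table: int = 1

    def seq(self) -> str:
        if self.kind == "codon":
            return "".join(self.codons)
        return "".join(self.nt)

    def __len__(self) -> int:
        return len(self.seq())


class _Locus:
    def __init__(self) -> None:
        self.parts: list[_Part] = []

    def add(self, part: _Part) -> _Part:
        self.parts.append(part)
        return part

    def fixed(self, name: str, nt: str, protect: bool = True) -> _Part:
        return self.add(_Part(name=name, kind="fixed", protect=protect, nt=list(nt)))

    def nc(self, name: str, nt: str) -> _Part:
        return self.add(_Part(name=name, kind="nc", nt=list(nt)))

    def coding(self, name: str, aa: str, codons: list[str], locked=(), table: int = 1) -> _Part:
        return self.add(
            _Part(name=name, kind="codon", aa=list(aa), codons=list(codons), locked=set(locked), table=table)
        )

    def seq(self) -> str:
        return "".join(p.seq() for p in self.parts)

    def offset(self, name: str) -> int:
        pos = 0
        for p in self.parts:
            if p.name == name:
                return pos
            pos += len(p)
        raise KeyError(name)

    def part(self, name: str) -> _Part:
        for p in self.parts:
            if p.name == name:
                return p
        raise KeyError(name)

    def locate(self, pos: int) -> tuple[_Part, int]:
        off = 0
        for p in self.parts:
            if off <= pos < off + len(p):
                return p, pos - off
            off += len(p)
        raise IndexError(pos)

    def try_edit(self, pos: int, accept: Callable[[], bool]) -> bool:
        """Attempt a minimal edit at ``pos`` that makes ``accept`` true.

        Non-coding bases may become any other base; coding positions only
        move within synonymous codons; protected parts and locked codons
        are untouchable.  The edit is reverted if ``accept`` stays false.
        """
        part, local = self.locate(pos)
        if part.protect:
            return False
        if part.kind == "nc":
            old = part.nt[local]
            for base in "CATG":
                if base == old:
                    continue
                part.nt[local] = base
                if accept():
                    return True
            part.nt[local] = old
            return False
        if part.kind == "codon":
            ci = local // 3
            if ci in part.nt_locked:
                return False  # synonymous edits allowed in motif codons, not here
            old = part.codons[ci]
            for alt in CODONS[part.table][part.aa[ci]]:
                if alt == old:
                    continue
                part.codons[ci] = alt
                if accept():
                    return True
            part.codons[ci] = old
            return False
        return False

    def kill_signal(self, interval: range, accept: Callable[[], bool]) -> bool:
        for pos in interval:
            if self.try_edit(pos, accept):
                return True
        return False


# --------------------------------------------------------------------------
# planted architecture description
# --------------------------------------------------------------------------


@dataclass
class PlantedIntron:
    donor: int
    branch: int
    acceptors: list[int]


@dataclass
class ArchitectureSpec:
    """What to plant.  Defaults are the study conditions; see docs."""

    kind: str
    seed: int = 0
    signal_strength: float = 1.0
    gc: float = 0.4
    divergence: float = 0.05
    n_introns: int = 7  # MULTI_INTRON_ALT3SS
    alt_intron_index: int = 1  # which intron carries the two 3'SS
    functional_retention: bool = True  # RETENTION_PAIR
    axis: str = subfun_caller.MOTIF_AXIS  # POST_WGD_PAIR
    corrupt_signals: bool = False  # allow divergence inside signals/motifs

    KINDS = (
        "ALT3SS",
        "MULTI_INTRON_ALT3SS",
        "ALT_TSS",
        "EXON_SKIP",
        "RETENTION_PAIR",
        "POST_WGD_PAIR",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise SpliceDupError(f"unknown architecture kind {self.kind!r}")
        if not 0 <= self.signal_strength <= 1:
            raise SpliceDupError("signal_strength must be in [0, 1]")


@dataclass
class GroundTruth:
    """Exact description of the emitted locus; consistent by construction."""

    kind: str
    introns: dict = field(default_factory=dict)  # gene id -> [PlantedIntron as dict]
    expected_isoforms: dict = field(default_factory=dict)  # gene id -> [event]
    expected_classes: dict = field(default_factory=dict)  # gene id -> {event: class}
    expected_localizations: dict = field(default_factory=dict)  # gene id -> {event: label}
    expected_mrnas: dict = field(default_factory=dict)  # gene id -> {event: mrna}
    motif_positions: dict = field(default_factory=dict)  # gene id -> {motif: nt offset}
    alt_start_nt: dict = field(default_factory=dict)  # gene id -> nt offset of S1 ATG
    expected_verdict: Optional[str] = None
    expected_mechanisms: dict = field(default_factory=dict)
    axis: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneratedLocus:
    spec: ArchitectureSpec
    genes: list
    model: SpliceSignalModel
    truth: GroundTruth

    @property
    def gene(self) -> GeneModel:
        return self.genes[0]


# --------------------------------------------------------------------------
# sampling helpers
# --------------------------------------------------------------------------


def _sample_nc(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _strip_atg(nt: list) -> None:
    """Remove ATG trinucleotides in place (leader regions stay start-free so
    the first-ATG rule lands on the annotated start)."""
    seq = "".join(nt)
    i = seq.find("ATG")
    while i != -1:
        nt[i + 1] = "C"
        seq = "".join(nt)
        i = seq.find("ATG")


def _sample_aa(rng, length: int, exclude: str = "") -> str:
    letters = [a for a in AA_ORDER if a not in exclude]
    w = np.array([AA_WEIGHTS[a] for a in letters])
    w = w / w.sum()
    return "".join(rng.choice(letters, size=length, p=w))


def _encode(rng, aa: str, table: int = 1) -> list[str]:
    return [CODONS[table][a][rng.integers(len(CODONS[table][a]))] for a in aa]


def _sample_signal(rng, pwm: PWM, strength: float) -> str:
    """A signal drawn from the PWM, pulled toward consensus by ``strength``."""
    if strength >= 1.0:
        return pwm.consensus
    letters = list("ACGT")
    out = []
    for i in range(len(pwm)):
        probs = pwm.probs[i].copy()
        one_hot = np.zeros(4)
        one_hot[int(np.argmax(probs))] = 1.0
        mix = strength * one_hot + (1 - strength) * probs
        mix = mix / mix.sum()
        out.append(rng.choice(letters, p=mix))
    return "".join(out)


def _plant(aa: list, motif_consensus: str, at: int) -> list[int]:
    """Overwrite aa[at:at+len] with a motif; returns locked indices."""
    if at + len(motif_consensus) > len(aa):
        raise SpliceDupError("motif does not fit in its region")
    for i, c in enumerate(motif_consensus):
        aa[at + i] = c
    return list(range(at, at + len(motif_consensus)))


# --------------------------------------------------------------------------
# sanitization against unplanted splice signals
# --------------------------------------------------------------------------


def _donor_ok(seq: str, d: int, model: SpliceSignalModel) -> bool:
    w = seq[d : d + len(model.donor_pwm)]
    if len(w) < len(model.donor_pwm) or not w.startswith("GT"):
        return False
    s = model.donor_pwm.score(w)
    return s is not None and s >= model.thresholds["donor"]


def _branch_ok(seq: str, b: int, model: SpliceSignalModel) -> bool:
    w = seq[b : b + len(model.branch_pwm)]
    if len(w) < len(model.branch_pwm):
        return False
    s = model.branch_pwm.score(w)
    return s is not None and s >= model.thresholds["branch"]


def _acceptor_ok(seq: str, a: int, model: SpliceSignalModel) -> bool:
    w = seq[a - 2 : a + 1]
    if len(w) < 3 or not w.endswith("AG"):
        return False
    s = model.acceptor_pwm.score(w)
    return s is not None and s >= model.thresholds["acceptor"]


def _first_problem(cands, planted: list[PlantedIntron]):
    by_donor = {p.donor: p for p in planted}
    for c in cands:
        p = by_donor.get(c.donor_pos)
        if p is None:
            return ("extra_candidate", c)
        if c.branch_pos != p.branch:
            return ("wrong_branch", c)
        got = [a for a, _ in c.acceptors]
        extra = [a for a in got if a not in p.acceptors]
        if extra:
            return ("extra_acceptor", (c, extra))
        missing = [a for a in p.acceptors if a not in got]
        if missing:
            return ("missing", p)
    found = {c.donor_pos for c in cands}
    for p in planted:
        if p.donor not in found:
            return ("missing", p)
    return None


def _local_acceptors(seq: str, lo: int, hi: int, model) -> set:
    return {
        z
        for z in range(max(2, lo), min(len(seq), hi))
        if _acceptor_ok(seq, z, model)
    }


def _kill(locus: _Locus, interval: range, model, target_dead: Callable[[str], bool]) -> bool:
    """Edit one position in ``interval`` so the target signal dies without
    creating any new acceptor nearby (guarantees sanitization terminates)."""
    lo, hi = interval.start - 6, interval.stop + 8
    before = _local_acceptors(locus.seq(), lo, hi, model)

    def accept() -> bool:
        seq = locus.seq()
        if not target_dead(seq):
            return False
        return _local_acceptors(seq, lo, hi, model) <= before

    return locus.kill_signal(interval, accept)


def _sanitize(locus: _Locus, model: SpliceSignalModel, planted: list[PlantedIntron], require_planted: bool) -> bool:
    def scan():
        return enumerate_introns(GeneModel(id="_scan", seq=locus.seq()), model)

    for _ in range(400):
        problem = _first_problem(scan(), planted)
        if problem is None:
            return True
        kind, payload = problem
        if kind == "missing":
            # a planted signal is absent (degraded by design at low signal
            # strength, or an edit was impossible without it)
            return not require_planted
        if kind == "extra_candidate":
            c = payload
            if _kill(
                locus,
                range(c.donor_pos, c.donor_pos + len(model.donor_pwm)),
                model,
                lambda seq, c=c: not _donor_ok(seq, c.donor_pos, model),
            ):
                continue
            if _kill(
                locus,
                range(c.branch_pos, c.branch_pos + len(model.branch_pwm)),
                model,
                lambda seq, c=c: not _branch_ok(seq, c.branch_pos, model),
            ):
                continue
            planted_accs = {a for p in planted for a in p.acceptors}
            killed = False
            for a, _s in c.acceptors:
                if a in planted_accs:
                    continue
                if _kill(locus, range(a - 2, a + 1), model, lambda seq, a=a: not _acceptor_ok(seq, a, model)):
                    killed = True
            if killed:
                continue
            return False
        if kind == "wrong_branch":
            c = payload
            if _kill(
                locus,
                range(c.branch_pos, c.branch_pos + len(model.branch_pwm)),
                model,
                lambda seq, c=c: not _branch_ok(seq, c.branch_pos, model),
            ):
                continue
            return False
        if kind == "extra_acceptor":
            c, extras = payload
            progress = False
            for a in extras:
                if _kill(locus, range(a - 2, a + 1), model, lambda seq, a=a: not _acceptor_ok(seq, a, model)):
                    progress = True
            if progress:
                continue
            return False
    return False


# --------------------------------------------------------------------------
# architecture builders
# --------------------------------------------------------------------------

UTR5, UTR3 = 21, 30


def _derived_sizes() -> tuple[int, int]:
    """Exon sizing (aa) derived from the 70/96 kDa study masses."""
    n_short = int(round((SHORT_ISOFORM_MASS - WATER) / MEAN_RESIDUE_MASS))
    n_alt = int(round((LONG_ISOFORM_MASS - SHORT_ISOFORM_MASS) / MEAN_RESIDUE_MASS))
    return n_short, n_alt


def _motif_consensus() -> dict[str, str]:
    return {mid: m.consensus for mid, m in load_motif_models().items()}


def _intron_nc(rng, locus: _Locus, tag: str, model, strength, gc, pad1: int, pad2: int = 8):
    """Append a non-coding intron: donor + pad + branch + pad + acceptor."""
    donor = locus.fixed(f"{tag}.donor", _sample_signal(rng, model.donor_pwm, strength))
    locus.nc(f"{tag}.pad1", _sample_nc(rng, pad1, gc))
    branch = locus.fixed(f"{tag}.branch", _sample_signal(rng, model.branch_pwm, strength))
    locus.nc(f"{tag}.pad2", _sample_nc(rng, pad2, gc))
    acc = locus.fixed(f"{tag}.acc", _sample_signal(rng, model.acceptor_pwm, strength))
    return donor, branch, acc


def _exon2_motif_layout(offsets: dict[str, int], exon2_aa: int):
    """Standard placements for S3/H1/G1-G5 on the terminal exon."""
    base = {"S3": 10, "H1": 40, "G1": 100, "G2": 130, "G3": 160, "G4": 190, "G5": 220}
    if exon2_aa < 240:
        raise SpliceDupError("terminal exon too short for the GTPase motif layout")
    offsets.update(base)
    return base


def _build_alt3ss_parts(rng, spec: ArchitectureSpec, model: SpliceSignalModel):
    """Shared plan for ALT3SS and the motif-axis POST_WGD ancestor."""
    mot = _motif_consensus()
    n_short, n_alt = _derived_sizes()
    exon1_aa = 180
    exon2_aa = n_short - exon1_aa

    locus = _Locus()
    utr = locus.nc("utr5", _sample_nc(rng, UTR5, spec.gc))
    _strip_atg(utr.nt)
    aa1 = list(_sample_aa(rng, exon1_aa))
    locked1 = _plant(aa1, "M", 0) + _plant(aa1, mot["NTD"], 10)
    locus.coding("exon1", "".join(aa1), _encode(rng, "".join(aa1)), locked=locked1)
    _intron_nc(rng, locus, "i1", model, spec.signal_strength, spec.gc, pad1=20)
    # alternative exon: S1/S2 between the two 3'SS; its final codon is the
    # distal acceptor (CAG = Gln at consensus)
    alt_aa = list(_sample_aa(rng, n_alt - 1))
    locked_alt = _plant(alt_aa, mot["S1"], 5) + _plant(alt_aa, mot["S2"], 5 + len(mot["S1"]) + 10)
    locus.coding("altexon", "".join(alt_aa), _encode(rng, "".join(alt_aa)), locked=locked_alt)
    locus.fixed("i1.acc_distal", _sample_signal(rng, model.acceptor_pwm, spec.signal_strength))
    aa2 = list(_sample_aa(rng, exon2_aa))
    offsets: dict[str, int] = {}
    locked2: list[int] = []
    for mid, at in _exon2_motif_layout(offsets, exon2_aa).items():
        locked2 += _plant(aa2, mot[mid], at)
    locus.coding("exon2", "".join(aa2), _encode(rng, "".join(aa2)), locked=locked2)
    locus.fixed("stop", "TAA")
    locus.nc("utr3", _sample_nc(rng, UTR3, spec.gc))

    d = locus.offset("i1.donor")
    b = locus.offset("i1.branch")
    a1 = locus.offset("i1.acc") + 2
    a2 = locus.offset("i1.acc_distal") + 2
    planted = PlantedIntron(donor=d, branch=b, acceptors=[a1, a2])
    return locus, planted, {"exon1_aa": exon1_aa, "alt_aa": n_alt, "exon2_aa": exon2_aa, "motifs": mot}


def _alt3ss_model(base: SpliceSignalModel, planted: PlantedIntron) -> SpliceSignalModel:
    """Widen the branch-to-acceptor window to cover the planted distal site."""
    span = planted.acceptors[-1] - planted.branch
    if span <= base.branch_to_acceptor_window[1]:
        return base
    cfg = base.to_config()
    cfg["branch_to_acceptor_window"] = [base.branch_to_acceptor_window[0], span + 20]
    cfg["max_intron_len"] = max(base.max_intron_len, planted.acceptors[-1] + 1 - planted.donor + 50)
    cfg["provenance"] = dict(cfg.get("provenance", {}), geometry="widened for planted alternative acceptor")
    return SpliceSignalModel.from_config(cfg)


def _gene_from_locus(
    locus: _Locus, gid: str, planted: list[PlantedIntron], cds_start: Optional[int], code=1, skippable=None
) -> GeneModel:
    seq = locus.seq()
    # exon annotation: constitutive (distal-most acceptor) exonic intervals
    bounds = []
    prev = 0
    for p in sorted(planted, key=lambda p: p.donor):
        bounds.append((prev, p.donor))
        prev = p.acceptors[-1] + 1
    bounds.append((prev, len(seq)))
    return GeneModel(
        id=gid,
        seq=seq,
        exons=bounds,
        cds_start=cds_start,
        genetic_code=code,
        source="synthetic",
        skippable_exons=list(skippable or []),
    )


def _excise(seq: str, intervals: list[tuple[int, int]]) -> str:
    out, prev = [], 0
    for s, e in sorted(intervals):
        out.append(seq[prev:s])
        prev = e
    out.append(seq[prev:])
    return "".join(out)


_MTS_WEIGHTS = {"L": 0.30, "S": 0.30, "A": 0.25, "T": 0.10, "P": 0.05}


def _sample_mts(rng, length: int) -> str:
    """Amphipathic presequence: an arginine every third residue keeps any
    hydropathy window well below the transmembrane threshold."""
    body = _sample_weighted(rng, _MTS_WEIGHTS, length)
    return "".join("R" if i % 3 == 0 else body[i] for i in range(length))
_TM_WEIGHTS = {"I": 0.4, "L": 0.3, "V": 0.2, "F": 0.1}
FWD = {tid: dict(CodonTable.unambiguous_dna_by_id[tid].forward_table) for tid in (1, 12)}


def _sample_weighted(rng, weights: dict[str, float], length: int) -> str:
    letters = sorted(weights)
    w = np.array([weights[a] for a in letters])
    return "".join(rng.choice(letters, size=length, p=w / w.sum()))


def _build_multi_intron(rng, spec: ArchitectureSpec, model: SpliceSignalModel):
    mot = _motif_consensus()
    n = spec.n_introns
    if n < 4:
        raise SpliceDupError("MULTI_INTRON_ALT3SS needs at least 4 introns for the motif layout")
    if spec.alt_intron_index != 1:
        raise SpliceDupError("the alternatively spliced intron is the second one in this architecture")
    locus = _Locus()
    locus.nc("utr5", _sample_nc(rng, UTR5, spec.gc))
    aa0 = list(_sample_aa(rng, 40))
    locked0 = _plant(aa0, "M", 0) + _plant(aa0, mot["NTD"], 5)
    locus.coding("exon0", "".join(aa0), _encode(rng, "".join(aa0)), locked=locked0)
    planted: list[PlantedIntron] = []

    def nc_intron(tag):
        _intron_nc(rng, locus, tag, model, spec.signal_strength, spec.gc, pad1=20)
        planted.append(
            PlantedIntron(
                donor=locus.offset(f"{tag}.donor"),
                branch=locus.offset(f"{tag}.branch"),
                acceptors=[locus.offset(f"{tag}.acc") + 2],
            )
        )

    nc_intron("i0")
    # long enough that the upstream intron's acceptor window cannot reach the
    # next planted acceptor
    aa1 = list(_sample_aa(rng, 50))
    locus.coding("exon1", "".join(aa1), _encode(rng, "".join(aa1)))
    # the second intron carries the two alternative 3' splice sites; S1 and
    # S2 sit between them so only the proximal (long) form encodes them
    _intron_nc(rng, locus, "ialt", model, spec.signal_strength, spec.gc, pad1=20)
    alt_aa = list(_sample_aa(rng, 19))
    locked_alt = _plant(alt_aa, mot["S1"], 0) + _plant(alt_aa, mot["S2"], 10)
    locus.coding("altexon", "".join(alt_aa), _encode(rng, "".join(alt_aa)), locked=locked_alt)
    locus.fixed("ialt.acc_distal", _sample_signal(rng, model.acceptor_pwm, spec.signal_strength))
    planted.append(
        PlantedIntron(
            donor=locus.offset("ialt.donor"),
            branch=locus.offset("ialt.branch"),
            acceptors=[locus.offset("ialt.acc") + 2, locus.offset("ialt.acc_distal") + 2],
        )
    )
    # remaining exons carry S3, H1 and the GTPase motifs
    queue = ["S3", "H1", "G1", "G2", "G3", "G4", "G5"]
    n_rest = n - 1  # terminal exons; introns = i0 + ialt + (n_rest - 1)
    per = [queue[i::n_rest] for i in range(n_rest)]
    for k in range(n_rest):
        aa_len = max(70, 15 + 23 * len(per[k]))
        aa = list(_sample_aa(rng, aa_len))
        locked = []
        for slot, mid in enumerate(per[k]):
            locked += _plant(aa, mot[mid], 5 + 23 * slot)
        locus.coding(f"exon{k + 2}", "".join(aa), _encode(rng, "".join(aa)), locked=locked)
        if k < n_rest - 1:
            nc_intron(f"i{k + 2}")
    locus.fixed("stop", "TAA")
    locus.nc("utr3", _sample_nc(rng, UTR3, spec.gc))
    planted.sort(key=lambda p: p.donor)
    return locus, planted, {"motifs": mot}


def _build_alt_tss(rng, spec: ArchitectureSpec, model: SpliceSignalModel):
    mot = _motif_consensus()
    n_short, _ = _derived_sizes()
    exon1_aa, table = 180, 12
    exon2_aa = n_short - exon1_aa
    locus = _Locus()
    locus.nc("utr5", _sample_nc(rng, UTR5, spec.gc))
    aa1 = list(_sample_aa(rng, exon1_aa))
    locked1 = _plant(aa1, "M", 0) + _plant(aa1, mot["NTD"], 10)
    locus.coding("exon1", "".join(aa1), _encode(rng, "".join(aa1), table), locked=locked1, table=table)
    locus.fixed("i1.donor", _sample_signal(rng, model.donor_pwm, spec.signal_strength))
    locus.nc("i1.pad1", _sample_nc(rng, 13, spec.gc))
    # the Ski7-coding stretch inside the intron, in the alternative-start frame
    s_aa = list(_sample_aa(rng, 22))
    locked_s = _plant(s_aa, mot["S1"], 0) + _plant(s_aa, mot["S2"], 11)
    locus.coding("s1region", "".join(s_aa), _encode(rng, "".join(s_aa), table), locked=locked_s, table=table)
    branch = _sample_signal(rng, model.branch_pwm, spec.signal_strength)
    locus.fixed("i1.branchjoin", "G" + branch + "A")  # V-L-T at consensus, stop-free in frame
    pad_aa = list(_sample_aa(rng, 3))
    locus.coding("i1.pad3", "".join(pad_aa), _encode(rng, "".join(pad_aa), table), table=table)
    locus.fixed("i1.acc", _sample_signal(rng, model.acceptor_pwm, spec.signal_strength))
    aa2 = list(_sample_aa(rng, exon2_aa))
    offsets: dict[str, int] = {}
    locked2 = []
    for mid, at in _exon2_motif_layout(offsets, exon2_aa).items():
        locked2 += _plant(aa2, mot[mid], at)
    locus.coding("exon2", "".join(aa2), _encode(rng, "".join(aa2), table), locked=locked2, table=table)
    locus.fixed("stop", "TAA")
    locus.nc("utr3", _sample_nc(rng, UTR3, spec.gc))
    planted = PlantedIntron(
        donor=locus.offset("i1.donor"),
        branch=locus.offset("i1.branchjoin") + 1,
        acceptors=[locus.offset("i1.acc") + 2],
    )
    return locus, planted, {"motifs": mot, "s1_nt": locus.offset("s1region")}


def _build_exon_skip(rng, spec: ArchitectureSpec, model: SpliceSignalModel):
    mot = _motif_consensus()
    locus = _Locus()
    locus.nc("utr5", _sample_nc(rng, UTR5, spec.gc))
    planted: list[PlantedIntron] = []

    def nc_intron(tag):
        _intron_nc(rng, locus, tag, model, spec.signal_strength, spec.gc, pad1=20)
        planted.append(
            PlantedIntron(
                donor=locus.offset(f"{tag}.donor"),
                branch=locus.offset(f"{tag}.branch"),
                acceptors=[locus.offset(f"{tag}.acc") + 2],
            )
        )

    aa0 = list(_sample_aa(rng, 60))
    locked0 = _plant(aa0, "M", 0) + _plant(aa0, mot["NTD"], 10)
    locus.coding("exon0", "".join(aa0), _encode(rng, "".join(aa0)), locked=locked0)
    nc_intron("i0")
    # cassette exon: carries S1/S2, length 0 mod 3 so skipping preserves frame
    aaS = list(_sample_aa(rng, 48))
    lockedS = _plant(aaS, mot["S1"], 5) + _plant(aaS, mot["S2"], 20)
    locus.coding("exonS", "".join(aaS), _encode(rng, "".join(aaS)), locked=lockedS)
    nc_intron("i1")
    aa2 = list(_sample_aa(rng, 60))
    locked2 = _plant(aa2, mot["S3"], 5) + _plant(aa2, mot["H1"], 30)
    locus.coding("exon2", "".join(aa2), _encode(rng, "".join(aa2)), locked=locked2)
    nc_intron("i2")
    aa3 = list(_sample_aa(rng, 320))
    locked3 = []
    for slot, mid in enumerate(["G1", "G2", "G3", "G4", "G5"]):
        locked3 += _plant(aa3, mot[mid], 30 + 60 * slot)
    locus.coding("exon3", "".join(aa3), _encode(rng, "".join(aa3)), locked=locked3)
    locus.fixed("stop", "TAA")
    locus.nc("utr3", _sample_nc(rng, UTR3, spec.gc))
    return locus, planted, {"motifs": mot}


def _build_retention(rng, spec: ArchitectureSpec, model: SpliceSignalModel):
    locus = _Locus()
    locus.nc("utr5", _sample_nc(rng, UTR5, spec.gc))
    if spec.functional_retention:
        exon1_aa = "M" + _sample_mts(rng, 29)
        locus.coding("exon1", exon1_aa, _encode(rng, exon1_aa), locked=range(30))
        locus.fixed("i1.donor", _sample_signal(rng, model.donor_pwm, spec.signal_strength))
        tm_aa = _sample_weighted(rng, _TM_WEIGHTS, 22)
        locus.coding("i1.tm", tm_aa, _encode(rng, tm_aa), locked=range(22))
        branch = _sample_signal(rng, model.branch_pwm, spec.signal_strength)
        locus.fixed("i1.branchjoin", "G" + branch + "A")
        pad_aa = _sample_aa(rng, 2, exclude="ILVF")
        locus.coding("i1.pad", pad_aa, _encode(rng, pad_aa))
        locus.fixed("i1.acc", _sample_signal(rng, model.acceptor_pwm, spec.signal_strength))
    else:
        # PTC7b-like: 103-nt intron, in-frame stop 20 codons into the ORF
        exon1_aa = "M" + _sample_mts(rng, 17)
        locus.coding("exon1", exon1_aa, _encode(rng, exon1_aa), locked=range(18))
        locus.fixed("i1.donor", _sample_signal(rng, model.donor_pwm, spec.signal_strength))
        locus.fixed("i1.stop", "TAA")
        locus.nc("i1.pad1", _sample_nc(rng, 76, spec.gc))
        locus.fixed("i1.branch", _sample_signal(rng, model.branch_pwm, spec.signal_strength))
        locus.nc("i1.pad2", _sample_nc(rng, 8, spec.gc))
        locus.fixed("i1.acc", _sample_signal(rng, model.acceptor_pwm, spec.signal_strength))
    exclude = "" if spec.functional_retention else "M"
    aa2 = list(_sample_mts(rng, 12)) + list(_sample_aa(rng, 238, exclude=exclude))
    locked2 = list(range(12))
    if not spec.functional_retention:
        # the only other in-frame ATG: eight codons upstream of the stop
        locked2 += _plant(aa2, "M", 242)
    locus.coding("exon2", "".join(aa2), _encode(rng, "".join(aa2)), locked=locked2)
    locus.fixed("stop", "TAA")
    locus.nc("utr3", _sample_nc(rng, UTR3, spec.gc))
    planted = PlantedIntron(
        donor=locus.offset("i1.donor"),
        branch=locus.offset("i1.branchjoin") + 1 if spec.functional_retention else locus.offset("i1.branch"),
        acceptors=[locus.offset("i1.acc") + 2],
    )
    return locus, planted, {}


# --------------------------------------------------------------------------
# divergence for duplicated pairs
# --------------------------------------------------------------------------


def _diverge(locus: _Locus, rng, rate: float, corrupt_signals: bool = False) -> None:
    """Per-site substitutions that respect signals, motifs and the ORF."""
    if rate <= 0:
        for part in locus.parts:
            if part.kind == "nc" and part.name in ("utr5", "pad5"):
                _strip_atg(part.nt)
        return
    for part in locus.parts:
        for i in range(len(part)):
            if rng.random() >= rate:
                continue
            if part.protect and not corrupt_signals:
                continue
            if part.kind == "nc":
                old = part.nt[i]
                choices = [b for b in "ACGT" if b != old]
                part.nt[i] = choices[rng.integers(3)]
            elif part.kind == "codon":
                ci = i // 3
                if ci in part.nt_locked or (ci in part.locked and not corrupt_signals):
                    continue
                codon = list(part.codons[ci])
                old = codon[i % 3]
                choices = [b for b in "ACGT" if b != old]
                codon[i % 3] = choices[rng.integers(3)]
                new = "".join(codon)
                if new in STOPS[part.table]:
                    continue  # purifying selection: no premature stops
                part.codons[ci] = new
                part.aa[ci] = FWD[part.table][new]
    for part in locus.parts:
        if part.kind == "nc" and part.name in ("utr5", "pad5"):
            _strip_atg(part.nt)


def _lock_junction(part_left: _Part, part_right: _Part, k_codons: int = 4) -> None:
    part_left.nt_locked.update(range(len(part_left.aa) - k_codons, len(part_left.aa)))
    part_right.nt_locked.update(range(k_codons))


def _drop_parts(locus: _Locus, names: set[str]) -> _Locus:
    out = _Locus()
    out.parts = [copy.deepcopy(p) for p in locus.parts if p.name not in names]
    return out


# --------------------------------------------------------------------------
# generate() and the suite
# --------------------------------------------------------------------------

_KIND_INDEX = {k: i for i, k in enumerate(ArchitectureSpec.KINDS)}


def _splice_all(seq: str, planted: list[PlantedIntron], alt_choice: dict[int, int] | None = None) -> str:
    choice = alt_choice or {}
    ivals = []
    for i, p in enumerate(planted):
        a = p.acceptors[choice.get(i, 0)]
        ivals.append((p.donor, a + 1))
    return _excise(seq, ivals)


def generate(spec: ArchitectureSpec, replicate: int = 0) -> GeneratedLocus:
    """Deterministically generate one locus (or gene trio) plus ground truth.

    Resamples the background (bounded) until the locus is clean: at signal
    strength 1.0 the candidate-intron scan must recover exactly the planted
    architecture, and at any strength no unplanted candidate may pass the
    default thresholds.
    """
    base = SpliceSignalModel.default()
    full = spec.signal_strength >= 1.0
    last_err = "no attempt"
    for attempt in range(40):
        rng = np.random.default_rng([spec.seed % (2**31), _KIND_INDEX[spec.kind], replicate, attempt])
        try:
            result = _generate_once(rng, spec, base, full)
        except _Resample as exc:
            last_err = str(exc)
            continue
        return result
    raise SpliceDupError(f"could not generate a clean {spec.kind} locus: {last_err}")


class _Resample(Exception):
    pass


def _require_clean(locus: _Locus, model, planted: list[PlantedIntron], full: bool, what: str) -> None:
    if not _sanitize(locus, model, planted, require_planted=full):
        raise _Resample(f"sanitization failed for {what}")


def _generate_once(rng, spec: ArchitectureSpec, base: SpliceSignalModel, full: bool) -> GeneratedLocus:
    kind = spec.kind
    truth = GroundTruth(kind=kind)
    if kind in ("ALT3SS", "POST_WGD_PAIR") and (kind == "ALT3SS" or spec.axis == subfun_caller.MOTIF_AXIS):
        locus, planted, meta = _build_alt3ss_parts(rng, spec, base)
        model = _alt3ss_model(base, planted)
        _require_clean(locus, model, [planted], full, "ALT3SS locus")
        seq = locus.seq()
        gid = "anc" if kind == "POST_WGD_PAIR" else "gene"
        gene = _gene_from_locus(locus, gid, [planted], cds_start=locus.offset("exon1"))
        truth.introns[gid] = [asdict(planted)]
        truth.expected_isoforms[gid] = [ALT3SS_PROXIMAL, ALT3SS_DISTAL]
        truth.expected_classes[gid] = {ALT3SS_PROXIMAL: DUAL, ALT3SS_DISTAL: HBS1_LIKE}
        truth.expected_mrnas[gid] = {
            ALT3SS_PROXIMAL: _excise(seq, [(planted.donor, planted.acceptors[0] + 1)]),
            ALT3SS_DISTAL: _excise(seq, [(planted.donor, planted.acceptors[1] + 1)]),
        }
        truth.motif_positions[gid] = {
            "S1": locus.offset("altexon") + 3 * 5,
            "NTD": locus.offset("exon1") + 3 * 10,
        }
        if kind == "ALT3SS":
            return GeneratedLocus(spec=spec, genes=[gene], model=model, truth=truth)
        return _derive_motif_pair(rng, spec, locus, planted, meta, model, gene, truth, full)

    if kind == "MULTI_INTRON_ALT3SS":
        locus, planted, meta = _build_multi_intron(rng, spec, base)
        _require_clean(locus, base, planted, full, "multi-intron locus")
        seq = locus.seq()
        gene = _gene_from_locus(locus, "gene", planted, cds_start=locus.offset("exon0"))
        alt_i = next(i for i, p in enumerate(planted) if len(p.acceptors) == 2)
        truth.introns["gene"] = [asdict(p) for p in planted]
        truth.expected_isoforms["gene"] = [ALT3SS_PROXIMAL, ALT3SS_DISTAL]
        truth.expected_classes["gene"] = {ALT3SS_PROXIMAL: DUAL, ALT3SS_DISTAL: HBS1_LIKE}
        truth.expected_mrnas["gene"] = {
            ALT3SS_PROXIMAL: _splice_all(seq, planted, {alt_i: 0}),
            ALT3SS_DISTAL: _splice_all(seq, planted, {alt_i: 1}),
        }
        return GeneratedLocus(spec=spec, genes=[gene], model=base, truth=truth)

    if kind == "ALT_TSS":
        locus, planted, meta = _build_alt_tss(rng, spec, base)
        _require_clean(locus, base, [planted], full, "ALT_TSS locus")
        seq = locus.seq()
        gene = _gene_from_locus(locus, "gene", [planted], cds_start=locus.offset("exon1"), code=12)
        s1_nt = meta["s1_nt"]
        truth.introns["gene"] = [asdict(planted)]
        truth.alt_start_nt["gene"] = s1_nt
        truth.expected_isoforms["gene"] = [CONSTITUTIVE, ALT_START]
        truth.expected_classes["gene"] = {CONSTITUTIVE: HBS1_LIKE, ALT_START: DUAL}
        truth.expected_mrnas["gene"] = {
            CONSTITUTIVE: _excise(seq, [(planted.donor, planted.acceptors[0] + 1)]),
            ALT_START: seq[s1_nt - 5 :],
        }
        return GeneratedLocus(spec=spec, genes=[gene], model=base, truth=truth)

    if kind == "EXON_SKIP":
        locus, planted, meta = _build_exon_skip(rng, spec, base)
        _require_clean(locus, base, planted, full, "exon-skip locus")
        seq = locus.seq()
        gene = _gene_from_locus(locus, "gene", planted, cds_start=locus.offset("exon0"), skippable=[1])
        base_mrna = _splice_all(seq, planted)
        cassette_len = len(locus.part("exonS"))
        m0 = gene.exons[0][1] - gene.exons[0][0]  # first exon block on the message
        skip_mrna = base_mrna[:m0] + base_mrna[m0 + cassette_len :]
        truth.introns["gene"] = [asdict(p) for p in planted]
        truth.expected_isoforms["gene"] = [CONSTITUTIVE, EXON_SKIP]
        truth.expected_classes["gene"] = {CONSTITUTIVE: DUAL, EXON_SKIP: HBS1_LIKE}
        truth.expected_mrnas["gene"] = {CONSTITUTIVE: base_mrna, EXON_SKIP: skip_mrna}
        return GeneratedLocus(spec=spec, genes=[gene], model=base, truth=truth)

    if kind == "RETENTION_PAIR":
        locus, planted, meta = _build_retention(rng, spec, base)
        _require_clean(locus, base, [planted], full, "retention locus")
        seq = locus.seq()
        gene = _gene_from_locus(locus, "gene", [planted], cds_start=locus.offset("exon1"))
        truth.introns["gene"] = [asdict(planted)]
        spliced = _excise(seq, [(planted.donor, planted.acceptors[0] + 1)])
        if spec.functional_retention:
            truth.expected_isoforms["gene"] = [CONSTITUTIVE, RETENTION]
            truth.expected_localizations["gene"] = {
                CONSTITUTIVE: MITOCHONDRIAL,
                RETENTION: NUCLEAR_ENVELOPE,
            }
            truth.expected_mrnas["gene"] = {CONSTITUTIVE: spliced, RETENTION: seq}
        else:
            truth.expected_isoforms["gene"] = [CONSTITUTIVE]
            truth.expected_localizations["gene"] = {CONSTITUTIVE: MITOCHONDRIAL}
            truth.expected_mrnas["gene"] = {CONSTITUTIVE: spliced}
        return GeneratedLocus(spec=spec, genes=[gene], model=base, truth=truth)

    if kind == "POST_WGD_PAIR":  # localization axis
        sub = ArchitectureSpec(kind="RETENTION_PAIR", seed=spec.seed, signal_strength=spec.signal_strength, gc=spec.gc)
        locus, planted, meta = _build_retention(rng, sub, base)
        _require_clean(locus, base, [planted], full, "retention ancestor")
        seq = locus.seq()
        anc = _gene_from_locus(locus, "anc", [planted], cds_start=locus.offset("exon1"))
        truth.introns["anc"] = [asdict(planted)]
        truth.expected_isoforms["anc"] = [CONSTITUTIVE, RETENTION]
        truth.expected_localizations["anc"] = {CONSTITUTIVE: MITOCHONDRIAL, RETENTION: NUCLEAR_ENVELOPE}
        return _derive_localization_pair(rng, spec, locus, planted, anc, truth, full)

    raise SpliceDupError(f"unhandled architecture {kind}")


def _derive_motif_pair(rng, spec, locus, planted, meta, model, anc_gene, truth, full) -> GeneratedLocus:
    """Hbs1-like paralog by precise intron excision; Ski7-like paralog by
    exon-1 loss plus a new start at motif S1 (H1 scrambled, G3 His -> Asn)."""
    mot = meta["motifs"]
    intron_parts = {"i1.donor", "i1.pad1", "i1.branch", "i1.pad2", "i1.acc", "altexon", "i1.acc_distal"}
    p1 = _drop_parts(locus, intron_parts)
    _lock_junction(p1.part("exon1"), p1.part("exon2"))
    _diverge(p1, rng, spec.divergence, spec.corrupt_signals)
    if not _sanitize(p1, model, [], require_planted=False):
        raise _Resample("paralog1 sanitization failed")

    p2 = _Locus()
    pad5 = p2.nc("pad5", _sample_nc(rng, 60, spec.gc))
    _strip_atg(pad5.nt)
    alt = copy.deepcopy(locus.part("altexon"))
    s1_codon = 5
    alt2 = _Part(
        name="altexon",
        kind="codon",
        aa=alt.aa[s1_codon:],
        codons=alt.codons[s1_codon:],
        locked={i - s1_codon for i in alt.locked if i >= s1_codon},
        table=alt.table,
    )
    p2.add(alt2)
    p2.add(copy.deepcopy(locus.part("i1.acc_distal")))
    exon2 = copy.deepcopy(locus.part("exon2"))
    h1_at, g3_at = 40, 160
    h1_len = len(mot["H1"])
    scramble = _sample_aa(rng, h1_len, exclude="".join(set(mot["H1"])))
    for i, a in enumerate(scramble):
        exon2.aa[h1_at + i] = a
        exon2.codons[h1_at + i] = CODONS[1][a][0]
        exon2.locked.discard(h1_at + i)
    his_idx = g3_at + mot["G3"].index("H")
    exon2.aa[his_idx] = "N"
    exon2.codons[his_idx] = "AAC"
    p2.add(exon2)
    p2.add(copy.deepcopy(locus.part("stop")))
    p2.add(copy.deepcopy(locus.part("utr3")))
    alt2.locked.add(0)  # the new initiation codon (S1's Met) must survive divergence
    _diverge(p2, rng, spec.divergence, spec.corrupt_signals)
    if not _sanitize(p2, model, [], require_planted=False):
        raise _Resample("paralog2 sanitization failed")

    g1 = GeneModel(id="p1", seq=p1.seq(), exons=[(0, len(p1.seq()))], cds_start=p1.offset("exon1"), source="synthetic")
    g2 = GeneModel(id="p2", seq=p2.seq(), exons=[(0, len(p2.seq()))], cds_start=p2.offset("altexon"), source="synthetic")
    truth.expected_classes["p1"] = {CONSTITUTIVE: HBS1_LIKE}
    truth.expected_classes["p2"] = {CONSTITUTIVE: SKI7_LIKE}
    truth.expected_verdict = subfun_caller.SUBFUNCTIONALIZED
    truth.axis = subfun_caller.MOTIF_AXIS
    truth.expected_mechanisms = {
        "p1": {"precise_intron_loss": True, "exon_loss_new_start": False},
        "p2": {"precise_intron_loss": False, "exon_loss_new_start": True},
    }
    return GeneratedLocus(spec=spec, genes=[anc_gene, g1, g2], model=model, truth=truth)


def _derive_localization_pair(rng, spec, locus, planted, anc_gene, truth, full) -> GeneratedLocus:
    """PTC7a-like paralog (donor disabled, TM retained in frame) and a
    PTC7b-like paralog (intron precisely excised, mitochondrial)."""
    base = SpliceSignalModel.default()
    p1 = _Locus()
    p1.parts = [copy.deepcopy(p) for p in locus.parts]
    p1.part("i1.donor").nt = list("GGTTGC")  # Gly-Cys in frame; no longer a donor
    _diverge(p1, rng, spec.divergence, spec.corrupt_signals)
    if not _sanitize(p1, base, [], require_planted=False):
        raise _Resample("localization paralog1 sanitization failed")

    intron_parts = {"i1.donor", "i1.tm", "i1.branchjoin", "i1.pad", "i1.acc"}
    p2 = _drop_parts(locus, intron_parts)
    _lock_junction(p2.part("exon1"), p2.part("exon2"))
    _diverge(p2, rng, spec.divergence, spec.corrupt_signals)
    if not _sanitize(p2, base, [], require_planted=False):
        raise _Resample("localization paralog2 sanitization failed")

    g1 = GeneModel(id="p1", seq=p1.seq(), exons=[(0, len(p1.seq()))], cds_start=p1.offset("exon1"), source="synthetic")
    g2 = GeneModel(id="p2", seq=p2.seq(), exons=[(0, len(p2.seq()))], cds_start=p2.offset("exon1"), source="synthetic")
    truth.expected_localizations["p1"] = {CONSTITUTIVE: NUCLEAR_ENVELOPE}
    truth.expected_localizations["p2"] = {CONSTITUTIVE: MITOCHONDRIAL}
    truth.expected_verdict = subfun_caller.SUBFUNCTIONALIZED
    truth.axis = subfun_caller.LOCALIZATION_AXIS
    truth.expected_mechanisms = {
        "p1": {"precise_intron_loss": False, "exon_loss_new_start": None},
        "p2": {"precise_intron_loss": True, "exon_loss_new_start": None},
    }
    return GeneratedLocus(spec=spec, genes=[anc_gene, g1, g2], model=base, truth=truth)



# --------------------------------------------------------------------------
# corpus generation
# --------------------------------------------------------------------------


@dataclass
class Corpus:
    loci: list  # (locus_id, GeneratedLocus)
    seed: int

    def manifest_rows(self) -> list[dict]:
        rows = []
        for lid, locus in self.loci:
            rows.append(
                {
                    "locus_id": lid,
                    "kind": locus.spec.kind,
                    "gene_ids": ";".join(g.id for g in locus.genes),
                    "signal_strength": locus.spec.signal_strength,
                    "divergence": locus.spec.divergence if locus.spec.kind == "POST_WGD_PAIR" else 0.0,
                    "seed": self.seed,
                }
            )
        return rows

    def write(self, out_dir) -> None:
        import os

        import pandas as pd

        from .seqio import write_fasta, write_gff3

        os.makedirs(out_dir, exist_ok=True)
        fasta_records = []
        gff_models = []
        truths = {}
        for lid, locus in self.loci:
            for g in locus.genes:
                rid = f"{lid}|{g.id}"
                fasta_records.append((rid, g.seq))
                gm = copy.deepcopy(g)
                gm.id = rid
                gm.origin = {"contig": rid, "strand": "+", "offset": 0, "gene_id": rid}
                gff_models.append(gm)
            truths[lid] = {
                "truth": locus.truth.to_dict(),
                "model": locus.model.to_config(),
                "spec": asdict(locus.spec),
            }
        write_fasta(fasta_records, os.path.join(out_dir, "corpus.fasta"))
        write_gff3(gff_models, os.path.join(out_dir, "corpus.gff3"))
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truths, fh, indent=2, sort_keys=True)
        pd.DataFrame(self.manifest_rows()).to_csv(
            os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False
        )


def generate_suite(
    n_per_architecture: int,
    seed: int,
    signal_strength: float = 1.0,
    divergence: float = 0.05,
    out_dir=None,
) -> Corpus:
    """A corpus of loci, ``n_per_architecture`` for each of the six
    architectures, with a manifest linking each locus to its ground truth.

    Deterministic for a fixed seed (byte-identical files on re-run).
    """
    if n_per_architecture < 1:
        raise SpliceDupError("n_per_architecture must be >= 1")
    loci = []
    for kind in ArchitectureSpec.KINDS:
        for j in range(n_per_architecture):
            spec = ArchitectureSpec(
                kind=kind,
                seed=seed,
                signal_strength=signal_strength,
                divergence=divergence,
            )
            loci.append((f"{kind}_{j:02d}", generate(spec, replicate=j)))
    corpus = Corpus(loci=loci, seed=seed)
    if out_dir is not None:
        corpus.write(out_dir)
    return corpus
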