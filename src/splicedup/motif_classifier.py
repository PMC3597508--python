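"""Ski7/Hbs1 diagnostic motifs and functional classification of isoforms.

Post-WGD Ski7 and Hbs1 proteins are distinguished by short conserved
sequence landmarks: S1-S3 (Ski7 N-terminus; S1 begins with a methionine),
H1 (the Hbs1 linker motif), the GTPase motifs G1-G5, and the structured
Hbs1 N-terminal domain (NTD).  A pre-duplication Ski7/Hbs1 protein carries
the full complement.  The catalytic histidine of motif G3 is diagnostic:
it is intact in functional Hbs1 GTPases and substituted (Ser/Asn/Asp) in
post-WGD Ski7s, so G3's special position is recorded but never scored —
a motif hit with a substituted His is still a hit.

Motif patterns ship as versioned config data (``data/motifs.json``), not
code: they are degenerate consensus strings where a position is a single
residue, a bracketed residue set (``[ST]``), or ``.`` (wildcard, unscored).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .models import DUAL, HBS1_LIKE, NEITHER, SKI7_LIKE, FunctionalClass, MotifHit, SpliceDupError

SKI7_REQUIRED = ("S1", "S2", "S3")
HBS1_REQUIRED = ("H1", "G1", "G2", "G3", "G4", "G5")


@dataclass
class MotifModel:
    """A degenerate-consensus motif with per-position residue sets."""

    id: str
    pattern: str
    threshold: float = 0.85  # fraction of the maximum score
    special_positions: dict = field(default_factory=dict)
    optional: bool = False
    positions: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not 0 < self.threshold <= 1:
            raise SpliceDupError(f"motif {self.id}: threshold must be in (0, 1]")
        self.positions = _parse_pattern(self.pattern)
        for name, idx in self.special_positions.items():
            if not 0 <= idx < len(self.positions):
                raise SpliceDupError(f"motif {self.id}: special position {name}={idx} out of range")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def consensus(self) -> str:
        """A representative exact-match sequence (first residue of each set)."""
        return "".join(sorted(p)[0] if p else "A" for p in self.positions)

    @property
    def max_score(self) -> float:
        special = set(self.special_positions.values())
        return float(sum(1 for i, p in enumerate(self.positions) if p and i not in special))

    def score(self, window: str) -> float:
        special = set(self.special_positions.values())
        return float(
            sum(
                1
                for i, p in enumerate(self.positions)
                if p and i not in special and window[i] in p
            )
        )


def _parse_pattern(pattern: str) -> list:
    """Expand 'M[ST]D.' into per-position residue sets (None = wildcard)."""
    positions = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            positions.append(set(pattern[i + 1 : j]))
            i = j + 1
        elif c == ".":
            positions.append(None)
            i += 1
        else:
            positions.append({c})
            i += 1
    return positions


def load_motif_models(path=None) -> dict[str, MotifModel]:
    """Motif models from a config file, defaulting to the packaged set."""
    if path is None:
        raw = resources.files("splicedup.data").joinpath("motifs.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    cfg = json.loads(raw)
    models = {}
    for m in cfg["motifs"]:
        models[m["id"]] = MotifModel(
            id=m["id"],
            pattern=m["pattern"],
            threshold=m.get("threshold", 0.85),
            special_positions=dict(m.get("special_positions", {})),
            optional=bool(m.get("optional", False)),
        )
    return models


def scan_motifs(protein: str, motif_models: dict[str, MotifModel]) -> list[MotifHit]:
    """Best above-threshold hit per motif, sorted by position along the protein.

    Motifs are unique landmarks in these proteins, so only the single best
    placement per motif is reported (leftmost on score ties).
    """
    if not protein:
        raise SpliceDupError("scan_motifs requires a non-empty protein")
    hits = []
    for mid, model in motif_models.items():
        w = len(model)
        best: MotifHit | None = None
        for pos in range(len(protein) - w + 1):
            s = model.score(protein[pos : pos + w])
            if best is None or s > best.score:
                best = MotifHit(
                    motif_id=mid,
                    start=pos,
                    score=s,
                    max_score=model.max_score,
                    special_residues={
                        name: protein[pos + idx]
                        for name, idx in model.special_positions.items()
                    },
                )
        if best is not None and best.score >= model.threshold * model.max_score:
            hits.append(best)
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


def catalytic_his_ok(g3_hit: MotifHit | None) -> bool:
    """True iff the catalytic residue of motif G3 is histidine.

    Post-WGD Ski7 proteins carry Ser, Asn or Asp here instead; any
    non-histidine residue fails.
    """
    if g3_hit is None:
        raise SpliceDupError("catalytic_his_ok requires a G3 hit")
    residue = g3_hit.special_residues.get("catalytic_his")
    if residue is None:
        raise SpliceDupError("G3 hit lacks a catalytic_his special position")
    return residue == "H"


def classify_isoform(hits: list[MotifHit]) -> FunctionalClass:
    """Assign SKI7_LIKE / HBS1_LIKE / DUAL / NEITHER from a motif hit set.

    Hbs1 criteria: H1 present, all of G1-G5 present, catalytic His intact.
    Ski7 criteria: S1, S2 and S3 present.  The NTD is recorded as
    supporting (never required) evidence for Hbs1 — in pre-duplication
    genes it sits on exon 1 and is present in both isoforms.  Motif order
    along the protein is a soft check: a violation downgrades confidence
    but never the class.
    """
    by_id = {}
    for h in hits:
        if h.motif_id not in by_id or h.score > by_id[h.motif_id].score:
            by_id[h.motif_id] = h

    evidence = []
    ski7_ok = True
    for mid in SKI7_REQUIRED:
        present = mid in by_id
        evidence.append((f"{mid}_present", present))
        ski7_ok &= present

    hbs1_ok = True
    for mid in HBS1_REQUIRED:
        present = mid in by_id
        evidence.append((f"{mid}_present", present))
        hbs1_ok &= present
    his_ok = "G3" in by_id and catalytic_his_ok(by_id["G3"])
    evidence.append(("catalytic_his_ok", his_ok))
    hbs1_ok &= his_ok

    evidence.append(("NTD_present_supporting", "NTD" in by_id))

    expected = [m for m in ("NTD", *SKI7_REQUIRED, "H1", "G1", "G2", "G3", "G4", "G5") if m in by_id]
    observed = sorted(expected, key=lambda m: by_id[m].start)
    evidence.append(("motif_order_canonical", observed == expected))

    if ski7_ok and hbs1_ok:
        label = DUAL
    elif ski7_ok:
        label = SKI7_LIKE
    elif hbs1_ok:
        label = HBS1_LIKE
    else:
        label = NEITHER
    return FunctionalClass(label=label, evidence=evidence)


def hits_to_tsv(protein_id: str, hits: list[MotifHit]) -> str:
    lines = ["protein\tmotif\tstart\tscore\tmax_score\tspecial"]
    for h in hits:
        special = ",".join(f"{k}:{v}" for k, v in sorted(h.special_residues.items()))
        lines.append(f"{protein_id}\t{h.motif_id}\t{h.start}\t{h.score:g}\t{h.max_score:g}\t{special}")
    return "\n".join(lines) + "\n"
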