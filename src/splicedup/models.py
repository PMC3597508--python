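"""Core domain types shared by all pipeline stages.

Coordinates are 0-based half-open on the sense strand throughout; GFF3 I/O
(:mod:`splicedup.seqio`) converts to and from the 1-based inclusive convention
of that format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

IUPAC_NT = set("ACGTURYSWKMBDHVN")

# isoform event labels
CONSTITUTIVE = "CONSTITUTIVE"
ALT3SS_PROXIMAL = "ALT3SS_PROXIMAL"
ALT3SS_DISTAL = "ALT3SS_DISTAL"
EXON_SKIP = "EXON_SKIP"
RETENTION = "RETENTION"
ALT_START = "ALT_START"

# functional classes (motif axis)
SKI7_LIKE = "SKI7_LIKE"
HBS1_LIKE = "HBS1_LIKE"
DUAL = "DUAL"
NEITHER = "NEITHER"

# localization classes
NUCLEAR_ENVELOPE = "NUCLEAR_ENVELOPE"
MITOCHONDRIAL = "MITOCHONDRIAL"
OTHER = "OTHER"


class SpliceDupError(Exception):
    """Base class for errors raised by this package."""


class ParseError(SpliceDupError):
    """A file could not be parsed; the message names the offending line."""


class CoordinateError(SpliceDupError):
    """Feature coordinates are inconsistent with the sequence."""


@dataclass
class GeneModel:
    """A gene locus on its sense strand.

    ``seq`` is always the sense (coding) strand; minus-strand GFF3 features
    are reverse-complemented on input.  ``exons`` are sorted, non-overlapping
    half-open intervals on ``seq``.  ``cds_start`` is the offset of the A of
    the annotated ATG, or ``None`` when no CDS was annotated.
    ``genetic_code`` is an NCBI translation table id: 1 (standard) or 12
    (alternative yeast nuclear, CUG = Ser, used by the CTG clade).
    ``skippable_exons`` lists exon indices annotated as cassette exons.
    ``origin`` optionally records the genomic placement (contig, strand,
    offset) so GFF3 round-trips preserve coordinates and strand.
    """

    id: str
    seq: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: Optional[int] = None
    genetic_code: int = 1
    source: str = ""
    skippable_exons: list[int] = field(default_factory=list)
    origin: Optional[dict] = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        bad = set(self.seq) - IUPAC_NT
        if bad:
            raise ParseError(f"gene {self.id}: illegal sequence characters {sorted(bad)}")
        self.exons = [tuple(e) for e in self.exons]
        prev_end = None
        for start, end in self.exons:
            if not (0 <= start < end <= len(self.seq)):
                raise CoordinateError(
                    f"gene {self.id}: exon [{start},{end}) outside sequence of length {len(self.seq)}"
                )
            if prev_end is not None and start < prev_end:
                raise CoordinateError(f"gene {self.id}: exons overlap or are unsorted")
            prev_end = end
        if self.cds_start is not None and self.exons:
            if not any(s <= self.cds_start < e for s, e in self.exons):
                raise CoordinateError(f"gene {self.id}: cds_start {self.cds_start} not within an exon")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Half-open intervals between consecutive annotated exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class IntronCandidate:
    """One donor + branch point + a ranked list of candidate 3' splice sites.

    ``donor_pos`` is the offset of the G of the GT dinucleotide (= intron
    start); ``acceptors`` are ``(acceptor_pos, score)`` pairs where
    ``acceptor_pos`` is the offset of the intron's final G, sorted
    proximal-to-distal (ascending).  A candidate with two or more acceptors
    is flagged alternatively spliced.
    """

    donor_pos: int
    branch_pos: int
    acceptors: list[tuple[int, float]]
    donor_score: float
    branch_score: float

    @property
    def alternative(self) -> bool:
        return len(self.acceptors) >= 2

    def intron_interval(self, acceptor_index: int = 0) -> tuple[int, int]:
        """Half-open genomic interval removed when splicing at the given acceptor."""
        acc, _ = self.acceptors[acceptor_index]
        return (self.donor_pos, acc + 1)


@dataclass
class Isoform:
    """An event-labelled transcript with its ORF consequences."""

    gene_id: str
    event: str
    event_detail: dict = field(default_factory=dict)
    mrna: str = ""
    cds: str = ""
    protein: str = ""
    premature_stop: bool = False
    stop_codon_offset: Optional[int] = None
    length_aa: int = 0
    mass_kda: float = 0.0

    @property
    def label(self) -> str:
        detail = ",".join(f"{k}={v}" for k, v in sorted(self.event_detail.items()))
        return f"{self.event}({detail})" if detail else self.event


@dataclass
class MotifHit:
    motif_id: str
    start: int
    score: float
    max_score: float
    special_residues: dict = field(default_factory=dict)


@dataclass
class FunctionalClass:
    label: str
    evidence: list = field(default_factory=list)


@dataclass
class TMPrediction:
    window_scores: list
    helices: list  # (start, end, mean hydropathy)
    n_terminal_tm: bool


@dataclass
class LocalizationCall:
    label: str
    evidence: dict = field(default_factory=dict)


@dataclass
class RetentionConsequence:
    frame_preserving: bool
    stop_free: bool
    functional_retention: bool
    stop_offset_aa: Optional[int] = None


@dataclass
class SubfunReport:
    verdict: str  # SUBFUNCTIONALIZED / REDUNDANT / INCOMPLETE_PARTITION / NOT_COMPARABLE
    axis: str  # MOTIF_COMPLEMENT or LOCALIZATION
    ancestor_classes: list = field(default_factory=list)
    paralog_classes: list = field(default_factory=list)
    mechanisms: dict = field(default_factory=dict)
    evidence: dict = field(default_factory=dict)


@dataclass
class AnalysisReport:
    """Serializable record of one gene's analysis; round-trips losslessly."""

    gene_id: str
    isoforms: list = field(default_factory=list)
    motif_hits: dict = field(default_factory=dict)
    classifications: dict = field(default_factory=dict)
    localizations: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                d = asdict(o)
                d["__type__"] = type(o).__name__
                return d
            raise TypeError(f"not serializable: {o!r}")

        return json.dumps(asdict(self), default=enc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        raw = json.loads(text)
        report = cls(gene_id=raw["gene_id"], provenance=raw.get("provenance", {}))
        report.isoforms = [_isoform_from_dict(d) for d in raw.get("isoforms", [])]
        report.motif_hits = {
            k: [MotifHit(**_strip(d)) for d in v] for k, v in raw.get("motif_hits", {}).items()
        }
        report.classifications = {
            k: FunctionalClass(**_strip(d)) for k, v in raw.get("classifications", {}).items()
            for d in [v]
        }
        report.localizations = {
            k: LocalizationCall(**_strip(d)) for k, v in raw.get("localizations", {}).items()
            for d in [v]
        }
        return report


def _strip(d: dict) -> dict:
    return {k: v for k, v in d.items() if k != "__type__"}


def _isoform_from_dict(d: dict) -> Isoform:
    d = _strip(d)
    d["event_detail"] = dict(d.get("event_detail", {}))
    return Isoform(**d)
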