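"""Domain records shared across the pipeline.

All coordinates at the package surface are 1-based and inclusive, the
GenBank/GFF3 convention; any half-open arithmetic is internal only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class FeatureRecord:
    """One annotated feature on a replicon.

    ``domain_tags`` carry the controlled functional vocabulary (see
    :mod:`mge_scout.vocab`) that downstream callers match on; ``product``
    is free text and never matched directly by the pipeline.
    """

    start: int
    end: int
    strand: str
    ftype: str
    product: str = ""
    domain_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid feature coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not isinstance(self.domain_tags, frozenset):
            object.__setattr__(self, "domain_tags", frozenset(self.domain_tags))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedReplicon:
    """One contig: sequence plus its ordered feature list."""

    id: str
    sequence: str
    features: list[FeatureRecord] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for feat in self.features:
            if feat.end > n:
                raise ValueError(
                    f"feature {feat.start}..{feat.end} outside contig "
                    f"{self.id} (length {n})"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.strand))

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_replicon(rep: AnnotatedReplicon) -> AnnotatedReplicon:
    """The same replicon read from the other strand: reverse-complemented
    sequence with mirrored feature coordinates and flipped strands."""
    from ._util import revcomp

    n = len(rep.sequence)
    feats = [
        FeatureRecord(
            start=n - f.end + 1,
            end=n - f.start + 1,
            strand="-" if f.strand == "+" else "+",
            ftype=f.ftype,
            product=f.product,
            domain_tags=f.domain_tags,
        )
        for f in rep.features
    ]
    return AnnotatedReplicon(
        id=rep.id, sequence=revcomp(rep.sequence), features=feats,
        source_path=rep.source_path,
    )


@dataclass
class ReadPairLink:
    """One mate pair mapped to a single contig (positions 1-based)."""

    pair_id: str
    contig: str
    pos1: int
    orient1: str
    pos2: int
    orient2: str


@dataclass
class RepeatPair:
    """Two repeat arms of equal length; direct or inverted orientation.

    For ``orientation="inverted"`` arm2 matches the reverse complement of
    arm1 at ``identity_percent`` (ungapped).  Arms never overlap and
    arm1 is always the leftmost arm.
    """

    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    orientation: str
    length_bp: int
    identity_percent: float

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.arm1_end - self.arm1_start + 1 != self.length_bp:
            raise ValueError("arm1 length disagrees with length_bp")
        if self.arm2_end - self.arm2_start + 1 != self.length_bp:
            raise ValueError("arm2 length disagrees with length_bp")
        if self.arm2_start <= self.arm1_end:
            raise ValueError("arms overlap or are out of order")


@dataclass
class TopologyCall:
    """Circular/linear/unresolved verdict with itemized evidence."""

    replicon_id: str
    verdict: str
    end_overlap_bp: int = 0
    spanning_pairs: int = 0
    tir: Optional[RepeatPair] = None
    evidence_notes: list[str] = field(default_factory=list)


@dataclass
class EsxLocus:
    """A called ESX (T7SS) locus.

    ``members`` are (feature index, core gene name) in genomic order;
    ``signature`` joins the gene names with "/" and marks the distal
    eccA convention with "-//-".
    """

    replicon_id: str
    members: list[tuple[int, str]]
    span_start: int
    span_end: int
    n_core: int
    signature: str
    assigned_type: str = "untyped"


#: Table-style feature flags, in report column order.
PROFILE_FLAGS = (
    "repA",
    "relaxase",
    "virD4",
    "virB4",
    "tcpC",
    "helicase",
    "dna_polymerase",
    "integrase",
    "transposase",
    "trna_genes",
    "t7ss",
    "toxin_antitoxin",
)


@dataclass
class ElementProfile:
    """Per-element feature matrix row plus derived classification."""

    replicon_id: str
    size_bp: int
    gc_percent: float
    n_cds: int
    topology: str
    flags: dict[str, bool]
    esx_loci: list[EsxLocus] = field(default_factory=list)
    classification: str = "unclassified"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key in PROFILE_FLAGS:
            self.flags.setdefault(key, False)


@dataclass
class IntegratedRegionCall:
    """A candidate integrated region delimited by a flanking direct repeat."""

    replicon_id: str
    dr: RepeatPair
    region_start: int
    region_end: int
    adjacent_transposase: Optional[int]
    cargo_summary: dict[str, int]


@dataclass
class SharedSegment:
    """A shared (syntenic) segment between elements A and B."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    identity_percent: float
    length_bp: int


@dataclass
class SharingSummary:
    """Totals over a non-overlapping (in A) set of shared segments."""

    shared_bp_a: int
    coverage_a_percent: float
    coverage_b_percent: float
    length_weighted_identity: float
    n_segments: int
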