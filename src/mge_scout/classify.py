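"""Element feature matrix, classification, and integrated-region calls.

The feature matrix records presence/absence of the backbone functions
that separate mobile-element classes: replication initiation (repA, or a
DnaB-like replicative helicase as the alternative marker), the
conjugation module (relaxase, VirB4, VirD4 coupling protein, TcpC), and
maintenance/mobility accessories (integrase, DDE transposase, tRNA
arrays, T7SS, toxin-antitoxin modules).

Classification is a fixed rule cascade over the flag vector (first match
wins):

1. putative ICE — conjugation module (relaxase plus VirB4 or VirD4) and
   an integrase or DDE transposase, without repA;
2. conjugative plasmid — replication marker plus relaxase plus VirB4 or
   VirD4;
3. cryptic plasmid — replication marker without relaxase;
4. unclassified otherwise.

Note one deliberate asymmetry: a replicon carrying VirB4 but no relaxase
has T4SS-like genes yet no mobilization function; the cascade leaves it
a cryptic plasmid and the profile notes the VirB4 presence rather than
promoting it.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

from .records import (
    AnnotatedReplicon,
    ElementProfile,
    EsxLocus,
    IntegratedRegionCall,
    RepeatPair,
    TopologyCall,
)
from .seqstats import gc_content

logger = logging.getLogger(__name__)

#: profile flag -> domain tag(s) that set it
_FLAG_TAGS = {
    "repA": ("RepA",),
    "relaxase": ("Relaxase",),
    "virD4": ("VirD4",),
    "virB4": ("VirB4",),
    "tcpC": ("TcpC",),
    "helicase": ("DnaB",),
    "dna_polymerase": ("PolI",),
    "integrase": ("Integrase",),
    "transposase": ("Transposase",),
}


def build_profile(
    replicon: AnnotatedReplicon,
    topo: TopologyCall,
    loci: Sequence[EsxLocus] = (),
) -> ElementProfile:
    """Assemble the per-element feature matrix row.

    Each backbone flag is true iff at least one feature carries the
    corresponding domain tag.  ``trna_genes`` counts tRNA features (or
    tRNA tags); ``t7ss`` is true iff ESX loci were called; the
    toxin-antitoxin flag requires a Toxin- and an Antitoxin-tagged
    feature adjacent with at most one intervening gene (a keyword/tag
    heuristic, noted as such in the report).
    """
    tag_union: set[str] = set()
    for f in replicon.features:
        tag_union |= f.domain_tags

    flags = {
        flag: any(t in tag_union for t in tags)
        for flag, tags in _FLAG_TAGS.items()
    }
    flags["trna_genes"] = any(
        f.ftype == "tRNA" or "tRNA" in f.domain_tags for f in replicon.features
    )
    flags["t7ss"] = len(loci) > 0
    flags["toxin_antitoxin"] = _has_adjacent_ta(replicon)

    notes: list[str] = []
    if flags["toxin_antitoxin"]:
        notes.append("TA call is a tag-adjacency heuristic")
    if flags["virB4"] and not flags["relaxase"]:
        notes.append("virB4 present without relaxase (incomplete conjugation module)")

    try:
        gc = gc_content(replicon.sequence)
    except ValueError:
        gc = float("nan")

    profile = ElementProfile(
        replicon_id=replicon.id,
        size_bp=len(replicon),
        gc_percent=gc,
        n_cds=sum(1 for f in replicon.features if f.ftype == "CDS"),
        topology=topo.verdict,
        flags=flags,
        esx_loci=list(loci),
        notes=notes,
    )
    profile.classification = classify_element(profile)
    return profile


def _has_adjacent_ta(replicon: AnnotatedReplicon) -> bool:
    feats = replicon.features
    toxin_idx = [i for i, f in enumerate(feats) if "Toxin" in f.domain_tags]
    anti_idx = [i for i, f in enumerate(feats) if "Antitoxin" in f.domain_tags]
    return any(
        abs(i - j) <= 2 and i != j for i in toxin_idx for j in anti_idx
    )


def classify_element(profile: ElementProfile) -> str:
    """Classify from the flag vector alone (pure function; see module
    docstring for the cascade)."""
    f = profile.flags
    replication = f["repA"] or f["helicase"]
    t4ss = f["virB4"] or f["virD4"]
    recombinase = f["integrase"] or f["transposase"]
    if f["relaxase"] and t4ss and recombinase and not f["repA"]:
        return "putative_ICE"
    if replication and f["relaxase"] and t4ss:
        return "conjugative_plasmid"
    if replication and not f["relaxase"]:
        return "cryptic_plasmid"
    return "unclassified"


def delimit_integrated_regions(
    replicon: AnnotatedReplicon,
    drs: Sequence[RepeatPair],
    max_adjacency: int = 1000,
) -> list[IntegratedRegionCall]:
    """Candidate integrated regions bounded by flanking direct repeats.

    Integration of a mobile element leaves same-orientation repeats at
    its boundaries, typically with a transposase next to one of them.
    One call is made per direct RepeatPair (identity >= 99%) whose
    inter-arm region contains at least one CDS; ``adjacent_transposase``
    is the nearest transposase/IS-tagged feature within
    ``max_adjacency`` bp of either arm, if any.  Calls are sorted by
    region length descending.
    """
    calls: list[IntegratedRegionCall] = []
    for dr in drs:
        if dr.orientation != "direct":
            logger.debug("skipping non-direct pair at %d", dr.arm1_start)
            continue
        if dr.identity_percent < 99.0:
            continue
        region_start = dr.arm1_end + 1
        region_end = dr.arm2_start - 1
        if region_end < region_start:
            continue
        inside = [
            f
            for f in replicon.features
            if f.start >= region_start and f.end <= region_end
        ]
        n_cds = sum(1 for f in inside if f.ftype == "CDS")
        if n_cds == 0:
            continue

        tn_idx = None
        tn_dist = max_adjacency + 1
        for idx, f in enumerate(replicon.features):
            if "Transposase" not in f.domain_tags:
                continue
            d = min(
                _interval_distance(f.start, f.end, dr.arm1_start, dr.arm1_end),
                _interval_distance(f.start, f.end, dr.arm2_start, dr.arm2_end),
            )
            if d < tn_dist:
                tn_dist, tn_idx = d, idx
        if tn_dist > max_adjacency:
            tn_idx = None

        calls.append(
            IntegratedRegionCall(
                replicon_id=replicon.id,
                dr=dr,
                region_start=region_start,
                region_end=region_end,
                adjacent_transposase=tn_idx,
                cargo_summary={
                    "n_cds": n_cds,
                    "n_trna": sum(1 for f in inside if f.ftype == "tRNA"),
                },
            )
        )
    calls.sort(key=lambda c: -(c.region_end - c.region_start + 1))
    return calls


def _interval_distance(a1: int, a2: int, b1: int, b2: int) -> int:
    """Gap in bp between two closed intervals; 0 when they touch/overlap."""
    if a2 < b1:
        return b1 - a2 - 1
    if b2 < a1:
        return a1 - b2 - 1
    return 0
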