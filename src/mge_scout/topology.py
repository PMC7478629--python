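"""Replicon topology calling from assembly evidence.

Three evidence channels decide whether a contig represents a circular or a
linear replicon:

* terminal sequence redundancy — an assembler presenting a circular
  molecule as a linear contig typically duplicates one terminus, so the
  contig's prefix equals its suffix exactly;
* read pairs spanning the two contig ends, each mate oriented outward
  toward its end, which is how a fragment across the circular junction
  maps after linearization;
* terminal inverted repeats (TIRs), the hallmark of linear
  (actinomycete-style) plasmids.

Circular evidence is physical and wins over a TIR; a contig with both is
called circular with the conflict recorded in the evidence notes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import AnnotatedReplicon, ReadPairLink, RepeatPair, TopologyCall
from .repeats import find_terminal_inverted_repeats

logger = logging.getLogger(__name__)


@dataclass
class TopologyParams:
    """Thresholds for topology calling (all configurable; no single
    standard exists, so defaults are deliberately liberal for draft
    assemblies)."""

    min_overlap: int = 20          # bp; smallest terminal redundancy accepted
    max_overlap: int = 2000        # bp; largest redundancy searched
    min_spanning_pairs: int = 3    # read pairs to call circular alone
    end_window: int = 500          # bp window at each end for mate placement
    tir_min_len: int = 50          # bp; TIR arm minimum
    # TIRs are near-perfect; a permissive floor would let the maximal
    # window dilute a perfect TIR with flanking noise, so the default
    # scan is exact and the threshold is exposed for degraded termini.
    tir_min_identity: float = 100.0
    tir_max_offset: int = 100      # bp; how far from the ends TIR arms may sit


def detect_end_overlap(
    sequence: str, min_overlap: int = 20, max_overlap: int = 2000
) -> int:
    """Largest L with prefix(sequence, L) == suffix(sequence, L) exactly.

    Returns 0 when no overlap in [min_overlap, max_overlap] exists.  The
    search is capped at half the sequence length so the two copies are
    disjoint; any window containing N fails (N matches nothing).
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    s = sequence.upper()
    n = len(s)
    hi = min(max_overlap, n // 2)
    for L in range(hi, min_overlap - 1, -1):
        head, tail = s[:L], s[n - L :]
        if head == tail and "N" not in head:
            return L
    return 0


def count_spanning_pairs(
    replicon: AnnotatedReplicon,
    links: Sequence[ReadPairLink],
    end_window: int = 500,
) -> int:
    """Read pairs with one mate at each contig end, oriented outward.

    A pair spans the (putative) circular junction when one mate lies in
    [1, end_window] on the minus strand (reading toward position 1) and
    the other in the last ``end_window`` bases on the plus strand
    (reading toward the end).
    """
    n = len(replicon)
    if end_window >= n / 2:
        raise ValueError("end_window must be smaller than half the contig")
    left_lo, left_hi = 1, end_window
    right_lo, right_hi = n - end_window + 1, n
    count = 0
    for link in links:
        if link.contig != replicon.id:
            logger.debug(
                "link %s maps to %s, not %s; ignored",
                link.pair_id, link.contig, replicon.id,
            )
            continue
        mates = ((link.pos1, link.orient1), (link.pos2, link.orient2))
        for (pa, oa), (pb, ob) in (mates, mates[::-1]):
            if (
                left_lo <= pa <= left_hi
                and oa == "-"
                and right_lo <= pb <= right_hi
                and ob == "+"
            ):
                count += 1
                break
    return count


def call_topology(
    replicon: AnnotatedReplicon,
    links: Optional[Sequence[ReadPairLink]] = None,
    params: Optional[TopologyParams] = None,
) -> TopologyCall:
    """Call a replicon circular, linear, or unresolved.

    Circular requires terminal redundancy >= min_overlap or spanning
    pairs >= min_spanning_pairs; linear requires a TIR with circular
    evidence below threshold; otherwise unresolved.  Every evidence field
    is populated regardless of verdict.
    """
    p = params or TopologyParams()
    overlap = detect_end_overlap(replicon.sequence, p.min_overlap, p.max_overlap)
    spanning = (
        count_spanning_pairs(replicon, links, p.end_window) if links else 0
    )
    tir: Optional[RepeatPair] = find_terminal_inverted_repeats(
        replicon, p.tir_max_offset, p.tir_min_len, p.tir_min_identity
    )

    notes: list[str] = []
    circular = overlap >= p.min_overlap or spanning >= p.min_spanning_pairs
    if overlap:
        notes.append(f"terminal redundancy of {overlap} bp")
    if spanning:
        notes.append(f"{spanning} end-spanning read pairs")
    if tir:
        notes.append(
            f"TIR {tir.length_bp} bp at {tir.identity_percent:.1f}% identity"
        )

    if circular:
        verdict = "circular"
        if tir:
            notes.append(
                "conflict: TIR present despite circular evidence; "
                "circular evidence is physical and wins"
            )
    elif tir is not None:
        verdict = "linear"
    else:
        verdict = "unresolved"

    call = TopologyCall(
        replicon_id=replicon.id,
        verdict=verdict,
        end_overlap_bp=overlap,
        spanning_pairs=spanning,
        tir=tir,
        evidence_notes=notes,
    )
    logger.info(
        "topology %s: %s (overlap=%d, spanning=%d, tir=%s)",
        replicon.id, verdict, overlap, spanning,
        tir.length_bp if tir else "none",
    )
    return call
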