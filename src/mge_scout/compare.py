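"""Shared-segment detection between two elements (anchor-and-chain).

Exact k-mer anchors between A and B (both strands of B) are grouped into
near-diagonal collinear chains; each chain defines a candidate segment
whose identity is then measured with a global edlib alignment of the two
spanned substrings.  Chains overlapping in A are resolved greedily by
anchor score, so the reported segment set is non-overlapping in A — this
is what coverage-of-A means.

Intended for nucleotide comparisons at roughly 80-100% identity
(homologous mobile elements, plasmid backbones); it is not a sensitive
protein-level or remote-homology aligner.
"""
from __future__ import annotations

import logging
from typing import Optional

import edlib
import numpy as np

from ._util import clean_sequence, revcomp
from .records import SharedSegment, SharingSummary

logger = logging.getLogger(__name__)


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


_XDROP = 30  # stop extending when score falls this far below its best
_MATCH, _MISMATCH = 1, -3


def _xdrop_extend(a: str, b: str, a_edge: int, b_edge: int, step: int) -> int:
    """Ungapped X-drop extension; returns the number of positions the
    edge moves.  ``step`` +1 extends right from half-open ends, -1
    extends left from closed starts."""
    best = score = 0
    best_off = 0
    off = 0
    while True:
        if step > 0:
            pa, pb = a_edge + off, b_edge + off
            if pa >= len(a) or pb >= len(b):
                break
        else:
            pa, pb = a_edge - 1 - off, b_edge - 1 - off
            if pa < 0 or pb < 0:
                break
        score += _MATCH if (a[pa] == b[pb] and a[pa] != "N") else _MISMATCH
        off += 1
        if score > best:
            best, best_off = score, off
        elif best - score > _XDROP:
            break
    return best_off


def _alignment_identity(sub_a: str, sub_b: str) -> float:
    """Percent identity from a global edit-distance alignment."""
    res = edlib.align(sub_a, sub_b, mode="NW", task="distance")
    dist = res["editDistance"]
    span = max(len(sub_a), len(sub_b))
    return 100.0 * (span - dist) / span if span else 0.0


def find_shared_segments(
    seq_a: str,
    seq_b: str,
    k: int = 21,
    min_segment: int = 1000,
    min_identity: float = 70.0,
    max_chain_gap: int = 2000,
    diagonal_band: int = 200,
    max_kmer_hits: int = 50,
) -> list[SharedSegment]:
    """Shared segments of A and B above a length and identity floor.

    Parameters
    ----------
    k:
        Anchor k-mer size (>= 15; exact matches of this length seed
        chains, so diverged homology below ~1 match per min_segment
        window is invisible).
    min_segment, min_identity:
        Reporting floors (bp in A; percent).
    max_chain_gap:
        Largest anchor-to-anchor gap (bp, in either sequence) bridged
        within one chain.
    diagonal_band:
        Allowed diagonal drift within a chain (absorbs indels).
    max_kmer_hits:
        K-mers with more B hits than this are skipped as repetitive.
    """
    if k < 15:
        raise ValueError("k must be >= 15")
    a = clean_sequence(seq_a)
    b = clean_sequence(seq_b)
    if not a or not b:
        return []

    segments: list[tuple[int, SharedSegment]] = []  # (score, segment)
    for strand in "+-":
        b_oriented = b if strand == "+" else revcomp(b)
        index = _kmer_positions(b_oriented, k)
        anchors: list[tuple[int, int]] = []  # (a_pos, b_pos in oriented B)
        for i in range(len(a) - k + 1):
            kmer = a[i : i + k]
            if "N" in kmer:
                continue
            hits = index.get(kmer)
            if hits and len(hits) <= max_kmer_hits:
                anchors.extend((i, j) for j in hits)
        if not anchors:
            continue

        # cluster by diagonal band, then split on large positional gaps
        anchors.sort(key=lambda t: (t[0] - t[1], t[0]))
        chains: list[list[tuple[int, int]]] = []
        for anc in anchors:
            placed = False
            for chain in reversed(chains):
                last = chain[-1]
                if abs((anc[0] - anc[1]) - (last[0] - last[1])) > diagonal_band:
                    break  # sorted by diagonal: earlier chains only further
                if 0 <= anc[0] - last[0] <= max_chain_gap + k:
                    chain.append(anc)
                    placed = True
                    break
            if not placed:
                chains.append([anc])

        chains = _merge_collinear(chains, max_chain_gap, diagonal_band)

        for chain in chains:
            a_lo = min(p for p, _ in chain)
            a_hi = max(p for p, _ in chain) + k  # half-open
            b_lo = min(q for _, q in chain)
            b_hi = max(q for _, q in chain) + k
            # recover diverged edges beyond the outermost exact anchors
            left = _xdrop_extend(a, b_oriented, a_lo, b_lo, step=-1)
            a_lo, b_lo = a_lo - left, b_lo - left
            right = _xdrop_extend(a, b_oriented, a_hi, b_hi, step=+1)
            a_hi, b_hi = a_hi + right, b_hi + right
            if a_hi - a_lo < min_segment:
                continue
            covered = set()
            for p, _ in chain:
                covered.update(range(p, p + k))
            score = len(covered)
            identity = _alignment_identity(
                a[a_lo:a_hi], b_oriented[b_lo:b_hi]
            )
            if identity < min_identity:
                continue
            if strand == "+":
                b_start, b_end = b_lo + 1, b_hi
            else:
                b_start = len(b) - b_hi + 1
                b_end = len(b) - b_lo
            segments.append(
                (
                    score,
                    SharedSegment(
                        a_start=a_lo + 1,
                        a_end=a_hi,
                        b_start=b_start,
                        b_end=b_end,
                        strand=strand,
                        identity_percent=identity,
                        length_bp=a_hi - a_lo,
                    ),
                )
            )

    # greedy resolution: best score first, drop segments overlapping in A
    segments.sort(key=lambda t: (-t[0], t[1].a_start))
    kept: list[SharedSegment] = []
    for _, seg in segments:
        if any(
            seg.a_start <= other.a_end and other.a_start <= seg.a_end
            for other in kept
        ):
            continue
        kept.append(seg)
    kept.sort(key=lambda s: s.a_start)
    logger.info("find_shared_segments: %d segment(s) kept", len(kept))
    return kept


def _merge_collinear(
    chains: list[list[tuple[int, int]]], max_gap: int, band: int
) -> list[list[tuple[int, int]]]:
    """Merge chains that continue each other (small gap, similar diagonal)."""
    def key(chain):
        return min(p for p, _ in chain)

    chains = sorted(chains, key=key)
    merged: list[list[tuple[int, int]]] = []
    for chain in chains:
        if merged:
            prev = merged[-1]
            pa, pb = max(prev, key=lambda t: t[0])
            ca, cb = min(chain, key=lambda t: t[0])
            if (
                0 <= ca - pa <= max_gap
                and abs((ca - cb) - (pa - pb)) <= band
                and cb >= pb
            ):
                prev.extend(chain)
                continue
        merged.append(list(chain))
    return merged


def summarize_sharing(
    segments: list[SharedSegment], len_a: int, len_b: int
) -> SharingSummary:
    """Coverage and identity totals over a segment set.

    Segments must be non-overlapping in A (as produced by
    :func:`find_shared_segments`); B-side intervals are merged before
    computing B coverage.  Identity is weighted by segment length in A.
    """
    if not segments:
        return SharingSummary(0, 0.0, 0.0, 0.0, 0)
    shared_a = sum(s.length_bp for s in segments)
    b_iv = sorted((s.b_start, s.b_end) for s in segments)
    merged: list[list[int]] = [list(b_iv[0])]
    for lo, hi in b_iv[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    shared_b = sum(hi - lo + 1 for lo, hi in merged)
    weights = np.array([s.length_bp for s in segments], dtype=float)
    idents = np.array([s.identity_percent for s in segments])
    return SharingSummary(
        shared_bp_a=shared_a,
        coverage_a_percent=100.0 * shared_a / len_a,
        coverage_b_percent=100.0 * shared_b / len_b,
        length_weighted_identity=float((weights * idents).sum() / weights.sum()),
        n_segments=len(segments),
    )
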