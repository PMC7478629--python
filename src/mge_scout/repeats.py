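"""Maximal direct/inverted repeat detection by seed-and-extend.

The finder reports every *maximal* ungapped repeat pair at or above a
length and identity threshold.  A pair is two equal-length, non-overlapping
arms; for inverted pairs arm2 matches the reverse complement of arm1.
Identity is ungapped (Hamming) over the aligned arms; N never matches.

A pair is maximal when extending both arms by one base on either side —
staying inside the sequence, keeping the arms disjoint — drops identity
below the threshold.  Every direct pair lives on one diagonal (fixed arm
offset) and every inverted pair on one anti-diagonal (fixed sum of arm
coordinates), so detection reduces to finding maximal above-threshold
windows over per-diagonal match arrays.  Candidate diagonals come from
exact k-mer seeds; the seed length is capped by a pigeonhole bound so that
any repeat passing the thresholds necessarily contains a seed, which makes
the search exhaustive, not heuristic.

Output determinism: pairs are sorted by length descending then arm1 start,
and when two pairs overlap on both arms only the longer (then leftmost)
is kept — this collapses the families of one-base-shifted near-duplicates
that arise at identity below 100%.
"""
from __future__ import annotations

import logging
from math import ceil, floor
from typing import Optional

import numpy as np

from ._util import clean_sequence, comp_array, seq_to_array
from .records import AnnotatedReplicon, RepeatPair

logger = logging.getLogger(__name__)

# identity comparisons in exact integer arithmetic: matches/length >= id/100
# <=> matches * 100_000 >= round(id * 1000) * length
_ID_SCALE = 1000


def _valid(matches: int, length: int, id_num: int) -> bool:
    return matches * 100 * _ID_SCALE >= id_num * length


def _guaranteed_seed_len(min_len: int, min_identity: float) -> int:
    """Longest k such that every qualifying repeat contains an exact k-run.

    Pigeonhole: an arm of length L with at most m mismatches contains an
    exact run of ceil((L - m) / (m + 1)).  Minimized over plausible L.
    """
    if min_identity >= 100:
        return min_len
    frac = 1.0 - min_identity / 100.0
    best = min_len
    for length in range(min_len, max(2000, 4 * min_len) + 1):
        m = floor(length * frac + 1e-12)
        if m >= length:
            return 1
        best = min(best, ceil((length - m) / (m + 1)))
    return best


def _maximal_windows(
    match: np.ndarray,
    min_len: int,
    id_num: int,
    max_len: Optional[int] = None,
) -> list[tuple[int, int, int]]:
    """All maximal windows (start, length, n_matches) over a 0/1 array.

    A window is valid when its match fraction passes ``id_num`` (scaled
    identity) and min_len <= length <= max_len; maximal when one-base
    extensions are invalid or blocked by the array bounds / max_len.
    Windows pinned at max_len slide; only the leftmost placement of each
    contiguous valid run is reported (the global both-arm-overlap filter
    makes the others redundant).
    """
    m = len(match)
    if m < min_len:
        return []
    match = match.astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(match)))
    # A[i] = scaled(csum[i]) - id_num * i ; window [i, j) valid iff A[j] >= A[i]
    scale = 100 * _ID_SCALE
    A = scale * csum - id_num * np.arange(m + 1, dtype=np.int64)

    out: list[tuple[int, int, int]] = []

    mism = np.flatnonzero(match == 0)
    lefts = np.concatenate(([0], mism + 1))
    rights = np.concatenate((mism, [m]))
    cap = max_len if max_len is not None else m + 1

    # windows strictly shorter than the cap: both edges flush on a
    # mismatch or an array bound
    r_vals = A[rights]
    # suffix max of A over right-candidate positions, for pruning
    suf = np.maximum.accumulate(r_vals[::-1])[::-1]
    for i in lefts:
        i = int(i)
        ai = A[i]
        lo = int(np.searchsorted(rights, i + min_len))
        for idx in range(lo, len(rights)):
            if suf[idx] < ai:
                break
            j = int(rights[idx])
            length = j - i
            if length >= cap:
                break
            if A[j] < ai:
                continue
            # maximal on the left: at bound or left extension invalid
            if i > 0 and A[j] >= A[i - 1]:
                continue
            # maximal on the right: at bound or right extension invalid
            if j < m and A[j + 1] >= ai:
                continue
            out.append((int(i), length, int(csum[j] - csum[i])))

    if max_len is not None and min_len <= max_len <= m:
        # windows pinned at the cap: every valid placement is maximal;
        # report the leftmost of each contiguous valid run
        w = cap
        sums = csum[w:] - csum[:-w]  # length m - w + 1
        ok = scale * sums >= id_num * w
        if ok.any():
            starts = np.flatnonzero(ok)
            keep = np.concatenate(([True], np.diff(starts) > 1))
            for s in starts[keep]:
                out.append((int(s), w, int(sums[s])))
    return out


def _seed_kmers(codes: np.ndarray, k: int) -> dict[bytes, np.ndarray]:
    """Positions of every exact k-mer (windows containing N excluded)."""
    n = len(codes)
    if n < k:
        return {}
    view = np.lib.stride_tricks.sliding_window_view(codes, k)
    has_n = (view == 4).any(axis=1)
    index: dict[bytes, list[int]] = {}
    raw = view.tobytes()
    for i in range(n - k + 1):
        if has_n[i]:
            continue
        key = raw[i * k : i * k + k]
        index.setdefault(key, []).append(i)
    return {k_: np.asarray(v) for k_, v in index.items()}


def _overlap_filter(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Keep longer (then leftmost) of pairs overlapping on both arms."""
    pairs = sorted(
        pairs, key=lambda p: (-p.length_bp, p.arm1_start, p.arm2_start)
    )
    kept: list[RepeatPair] = []
    for cand in pairs:
        clash = False
        for acc in kept:
            if (
                cand.orientation == acc.orientation
                and cand.arm1_start <= acc.arm1_end
                and acc.arm1_start <= cand.arm1_end
                and cand.arm2_start <= acc.arm2_end
                and acc.arm2_start <= cand.arm2_end
            ):
                clash = True
                break
        if not clash:
            kept.append(cand)
    return kept


def find_repeats(
    sequence: str,
    orientation: str = "both",
    min_len: int = 100,
    min_identity: float = 100.0,
) -> list[RepeatPair]:
    """Find all maximal direct and/or inverted repeat pairs.

    Parameters
    ----------
    sequence:
        Nucleotide string; characters outside {A,C,G,T} are treated as N
        and never match.
    orientation:
        "direct", "inverted", or "both".
    min_len:
        Minimum arm length in bp (>= 20 recommended; shorter floods the
        output with chance matches).
    min_identity:
        Minimum ungapped arm identity, percent (80-100).

    Returns
    -------
    list of RepeatPair sorted by length descending, then arm1 start.
    Sequences shorter than ``2 * min_len`` yield an empty list.
    """
    if orientation not in ("direct", "inverted", "both"):
        raise ValueError(f"bad orientation {orientation!r}")
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must be in (0, 100]")
    seq = clean_sequence(sequence)
    n = len(seq)
    if n < 2 * min_len:
        return []
    codes = seq_to_array(seq)
    comp = comp_array(codes)
    id_num = int(round(min_identity * _ID_SCALE))

    k = max(4, min(21, _guaranteed_seed_len(min_len, min_identity), min_len))
    index = _seed_kmers(codes, k)
    logger.debug(
        "repeat scan: n=%d k=%d min_len=%d min_identity=%s", n, k, min_len,
        min_identity,
    )

    pairs: list[RepeatPair] = []

    if orientation in ("direct", "both"):
        diags: set[int] = set()
        for pos in index.values():
            if len(pos) < 2:
                continue
            diffs = pos[None, :] - pos[:, None]
            diags.update(int(d) for d in diffs[diffs > 0].ravel())
        for d in sorted(diags):
            if d < min_len or n - d < min_len:
                continue
            match = (codes[: n - d] == codes[d:]) & (codes[: n - d] != 4)
            for start, length, matches in _maximal_windows(
                match, min_len, id_num, max_len=d
            ):
                pairs.append(
                    RepeatPair(
                        arm1_start=start + 1,
                        arm1_end=start + length,
                        arm2_start=start + d + 1,
                        arm2_end=start + d + length,
                        orientation="direct",
                        length_bp=length,
                        identity_percent=100.0 * matches / length,
                    )
                )

    if orientation in ("inverted", "both"):
        antidiags: set[int] = set()
        rc_index: dict[bytes, np.ndarray] = {}
        for key, pos in index.items():
            rc_key = bytes(3 - b if b < 4 else 4 for b in key)[::-1]
            rc_index.setdefault(rc_key, pos)
        for key, pos in index.items():
            partners = rc_index.get(key)
            if partners is None:
                continue
            for p in pos:
                for q in partners:
                    antidiags.add(int(p) + int(q) + k - 1)
        for c in sorted(antidiags):
            lo = max(0, c - (n - 1))
            rlim = (c - 1) // 2  # arm1 may extend to here (inclusive)
            if rlim - lo + 1 < min_len:
                continue
            p = np.arange(lo, rlim + 1)
            match = (codes[p] == comp[c - p]) & (codes[p] != 4)
            for start, length, matches in _maximal_windows(
                match, min_len, id_num
            ):
                a = lo + start
                pairs.append(
                    RepeatPair(
                        arm1_start=a + 1,
                        arm1_end=a + length,
                        arm2_start=c - a - length + 2,
                        arm2_end=c - a + 1,
                        orientation="inverted",
                        length_bp=length,
                        identity_percent=100.0 * matches / length,
                    )
                )

    kept = _overlap_filter(pairs)
    kept.sort(key=lambda x: (-x.length_bp, x.arm1_start, x.arm2_start))
    logger.info(
        "find_repeats: %d candidate pairs, %d after overlap filter",
        len(pairs), len(kept),
    )
    return kept


def find_terminal_inverted_repeats(
    replicon: AnnotatedReplicon | str,
    max_offset: int = 100,
    min_len: int = 50,
    min_identity: float = 100.0,
) -> Optional[RepeatPair]:
    """Longest inverted repeat pinned to both ends of a replicon.

    Returns the longest inverted pair whose arm1 starts within
    ``max_offset`` of position 1 and whose arm2 ends within ``max_offset``
    of the sequence end — the terminal inverted repeat (TIR) architecture
    of linear plasmids — or None.
    """
    seq = replicon.sequence if isinstance(replicon, AnnotatedReplicon) else replicon
    n = len(seq)
    candidates = [
        p
        for p in find_repeats(seq, "inverted", min_len, min_identity)
        if p.arm1_start - 1 <= max_offset and n - p.arm2_end <= max_offset
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda p: (p.length_bp, p.identity_percent))
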