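"""Repeat finder: constructed cases, brute-force oracle equivalence,
planted-truth recovery, and symmetry properties."""
import numpy as np
import pytest

from mge_scout import (
    find_repeats,
    find_terminal_inverted_repeats,
    generate_linear_plasmid,
)
from mge_scout._util import revcomp

from conftest import random_seq

# ---------------------------------------------------------------------------
# independent brute-force oracle
#
# Enumerates every (arm placement, length) combination per (anti)diagonal
# with full numpy matrices — no seeding, no candidate-edge shortcuts —
# then applies the documented output policy: maximality under one-base
# extensions, leftmost placement for separation-capped direct windows,
# and the longer-wins filter for pairs overlapping on both arms.


def _valid_matrix(match, min_len, min_identity, cap):
    m = len(match)
    c = np.concatenate(([0], np.cumsum(match.astype(np.int64))))
    max_l = min(cap, m)
    lengths = np.arange(1, max_l + 1)
    starts = np.arange(m)
    ends = starts[:, None] + lengths[None, :]
    inb = ends <= m
    sums = np.where(inb, c[np.minimum(ends, m)] - c[starts][:, None], -1)
    num = int(round(min_identity * 1000))
    valid = inb & (sums * 100_000 >= num * ends - num * starts[:, None]) & (
        lengths[None, :] >= min_len
    )
    return valid


def _maximal_from_valid(valid, cap):
    m, max_l = valid.shape
    out = []
    for i in range(m):
        for li in range(max_l):
            if not valid[i, li]:
                continue
            L = li + 1
            if L == cap:
                continue  # handled as capped runs below
            right_ok = li + 1 < max_l and i + L + 1 <= m and valid[i, li + 1]
            left_ok = li + 1 < max_l and i >= 1 and valid[i - 1, li + 1]
            if not right_ok and not left_ok:
                out.append((i, L))
    if cap <= max_l:
        run_prev = False
        for i in range(m):
            v = valid[i, cap - 1]
            if v and not run_prev:
                out.append((i, cap))
            run_prev = v
    return out


def _overlap_filter(pairs):
    pairs = sorted(pairs, key=lambda p: (-p[4], p[0], p[2]))
    kept = []
    for c in pairs:
        if not any(
            c[0] <= a[1] and a[0] <= c[1] and c[2] <= a[3] and a[2] <= c[3]
            for a in kept
        ):
            kept.append(c)
    return kept


def oracle_repeats(seq, orientation, min_len, min_identity):
    """All maximal repeat pairs as (a1s, a1e, a2s, a2e, L) 1-based tuples."""
    n = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_map = {65: 84, 84: 65, 67: 71, 71: 67}
    comp = np.array([comp_map.get(int(b), 0) for b in codes], dtype=np.uint8)
    found = []
    if orientation in ("direct", "both"):
        for d in range(1, n):
            m = n - d
            if m < min_len:
                continue
            match = codes[:m] == codes[d:]
            valid = _valid_matrix(match, min_len, min_identity, cap=d)
            for i, L in _maximal_from_valid(valid, cap=d):
                found.append((i + 1, i + L, i + d + 1, i + d + L, L))
    if orientation in ("inverted", "both"):
        for c in range(2 * min_len - 1, 2 * n - 2):
            lo = max(0, c - (n - 1))
            rlim = (c - 1) // 2
            if rlim - lo + 1 < min_len:
                continue
            p = np.arange(lo, rlim + 1)
            match = codes[p] == comp[c - p]
            valid = _valid_matrix(match, min_len, min_identity, cap=len(p) + 1)
            for i, L in _maximal_from_valid(valid, cap=len(p) + 1):
                a = lo + i
                found.append((a + 1, a + L, c - a - L + 2, c - a + 1, L))
    return sorted(_overlap_filter(found))


def _as_tuples(pairs):
    return sorted(
        (p.arm1_start, p.arm1_end, p.arm2_start, p.arm2_end, p.length_bp)
        for p in pairs
    )


def _plant(rng, n=420):
    """Random sequence with planted direct + inverted repeats, some
    degraded, so the oracle comparison is non-trivial."""
    s = list(random_seq(rng, n))
    arm_d = random_seq(rng, 34)
    s[10:44] = arm_d
    degraded = list(arm_d)
    for pos in rng.choice(34, 2, replace=False):
        degraded[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[degraded[pos]]
    s[150 : 150 + 34] = degraded
    arm_i = random_seq(rng, 28)
    s[220 : 220 + 28] = arm_i
    s[330 : 330 + 28] = revcomp(arm_i)
    return "".join(s)


@pytest.mark.parametrize("min_identity", [100.0, 90.0])
@pytest.mark.parametrize("orientation", ["direct", "inverted"])
def test_oracle_equivalence(orientation, min_identity):
    """Seed-and-extend finds exactly the brute-force maximal pair set."""
    for seed in range(10):
        rng = np.random.Generator(np.random.PCG64(1000 + seed))
        seq = _plant(rng)
        got = _as_tuples(find_repeats(seq, orientation, 20, min_identity))
        expected = oracle_repeats(seq, orientation, 20, min_identity)
        assert got == expected, f"seed {seed}"


def test_constructed_palindrome():
    """X + revcomp(X) yields one inverted pair spanning everything."""
    rng = np.random.Generator(np.random.PCG64(11))
    x = random_seq(rng, 60)
    pairs = find_repeats(x + revcomp(x), "inverted", 20, 100.0)
    assert [
        (p.arm1_start, p.arm1_end, p.arm2_start, p.arm2_end, p.length_bp,
         p.identity_percent)
        for p in pairs
    ] == [(1, 60, 61, 120, 60, 100.0)]


def test_short_sequence_empty():
    assert find_repeats("ACGTACGT", "both", 20, 100.0) == []


def test_n_never_matches():
    arm = "ACGTTGCAACGTTGCAACGTTGCA"  # 24 bp
    filler = "CATCATGGTTAACCGGATCGATCG" * 3
    seq = arm + filler + arm
    assert find_repeats(seq, "direct", 20, 100.0)
    seq_n = arm + filler + arm[:10] + "N" * 4 + arm[14:]
    found = find_repeats(seq_n, "direct", 20, 100.0)
    assert all(p.length_bp < 14 or "N" not in seq_n[p.arm2_start - 1 : p.arm2_end]
               for p in found)


def test_reverse_complement_symmetry():
    """Inverted pairs of revcomp(s) are the coordinate mirror of s's."""
    rng = np.random.Generator(np.random.PCG64(77))
    seq = _plant(rng)
    n = len(seq)
    fwd = _as_tuples(find_repeats(seq, "inverted", 20, 100.0))
    rev = find_repeats(revcomp(seq), "inverted", 20, 100.0)
    mirrored = sorted(
        (n - p.arm2_end + 1, n - p.arm2_start + 1,
         n - p.arm1_end + 1, n - p.arm1_start + 1, p.length_bp)
        for p in rev
    )
    assert fwd == mirrored


class TestTerminalInvertedRepeats:
    def test_planted_perfect_tir_489(self):
        """A 21.6 kb linear plasmid with a planted 489 bp perfect TIR is
        recovered with exact coordinates."""
        rep, truth = generate_linear_plasmid(21_616, 489, seed=7)
        tir = find_terminal_inverted_repeats(rep)
        assert tir is not None
        assert (tir.arm1_start, tir.arm1_end) == (1, 489)
        assert (tir.arm2_start, tir.arm2_end) == (21_616 - 489 + 1, 21_616)
        assert tir.identity_percent == 100.0

    def test_planted_degraded_tir_101(self):
        """A 101 bp TIR at 99% planted identity is recovered at >= 99
        and < 100 percent identity."""
        rep, truth = generate_linear_plasmid(8_000, 101, tir_identity=99.0,
                                             seed=3)
        tir = find_terminal_inverted_repeats(
            rep, min_len=50, min_identity=99.0
        )
        assert tir is not None
        assert tir.length_bp >= 99
        assert 99.0 <= tir.identity_percent < 100.0

    def test_duplicated_terminus_is_not_tir(self):
        """Direct (circular-style) terminal duplication must not be
        mistaken for a TIR."""
        rng = np.random.Generator(np.random.PCG64(5))
        core = random_seq(rng, 3000)
        seq = core + core[:120]
        assert find_terminal_inverted_repeats(seq) is None
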