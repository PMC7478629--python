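"""Synthetic replicon generator with fully known planted truth.

Every fixture is generated from a seed through numpy's PCG64 generator
(a named, portable PRNG: identical byte output on every platform for the
same seed), on a repeat-free random background, with mobile-element
architecture planted at recorded coordinates:

* linear plasmids — terminal inverted repeats (TIRs) of configurable
  length and identity, optionally an internal inverted-repeat-flanked
  region carrying a tRNA array with transposases at the flanks;
* circular plasmids — presented as linear contigs with a duplicated
  terminus plus read-pair links spanning the two ends (with an optional
  mate-mispairing noise rate);
* ICE-like elements — cargo flanked by direct repeats with a transposase
  adjacent to one arm, ESX core-gene clusters laid out in configurable
  gene orders, and a domain-tagged backbone gene complement.

Annotations are synthesized directly with domain tags set, so no gene
caller sits in the test loop.  The returned SyntheticTruth records every
planted coordinate and rate; it is sufficient to score any downstream
module without re-deriving anything.

Backgrounds are rejection-sampled to contain no unplanted repeat at or
above ``verify_min_len`` bp at 100% identity; the check runs for
fixtures up to 50 kb (above that the chance of a spurious exact repeat
of that length is negligible and the scan cost is not).
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._util import revcomp
from .records import AnnotatedReplicon, FeatureRecord, ReadPairLink
from .repeats import find_repeats
from .vocab import GAP_MARK, GENE_TO_TAG

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: planted-gene geometry (bp)
ESX_GENE_LEN = 1400
ESX_GENE_GAP = 500
ECCA_GAP = 17000
BACKBONE_GENE_LEN = 1200
BACKBONE_GENE_GAP = 300

VERIFY_MIN_LEN = 50
VERIFY_MAX_BP = 50_000


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized beside every fixture."""

    seed: int
    replicon_id: str
    topology: str
    end_overlap: int = 0
    tir: Optional[dict] = None
    dr_pairs: list[dict] = field(default_factory=list)
    inverted_pairs: list[dict] = field(default_factory=list)
    esx_clusters: list[dict] = field(default_factory=list)
    backbone_flags: list[str] = field(default_factory=list)
    shared_segments: list[dict] = field(default_factory=list)
    links: Optional[dict] = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def _random_seq_array(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Random sequence with base counts matching ``gc`` exactly (to
    rounding), as a byte array."""
    n_gc = int(round(length * gc / 100.0))
    n_g = n_gc // 2
    n_c = n_gc - n_g
    n_at = length - n_gc
    n_a = n_at // 2
    n_t = n_at - n_a
    arr = np.concatenate(
        [
            np.full(n_a, ord("A"), dtype=np.uint8),
            np.full(n_c, ord("C"), dtype=np.uint8),
            np.full(n_g, ord("G"), dtype=np.uint8),
            np.full(n_t, ord("T"), dtype=np.uint8),
        ]
    )
    rng.shuffle(arr)
    return arr


def _planted_regions_ok(
    seq: str, planted: list[tuple[int, int]], min_len: int
) -> bool:
    """True when every repeat >= min_len at 100% identity hits a planted
    region with both arms."""
    for pair in find_repeats(seq, "both", min_len=min_len, min_identity=100.0):
        for arm_lo, arm_hi in (
            (pair.arm1_start, pair.arm1_end),
            (pair.arm2_start, pair.arm2_end),
        ):
            if not any(
                arm_lo <= hi and lo <= arm_hi for lo, hi in planted
            ):
                return False
    return True


def _mutate_arm(
    rng: np.random.Generator, arm: np.ndarray, identity: float
) -> tuple[np.ndarray, float]:
    """Substitute bases to degrade an arm to ~identity percent; returns
    the mutated copy and the exact resulting identity."""
    n = len(arm)
    n_mut = int(round(n * (1.0 - identity / 100.0)))
    out = arm.copy()
    if n_mut:
        sites = rng.choice(n, size=n_mut, replace=False)
        for s in sites:
            choices = _BASES[_BASES != out[s]]
            out[s] = rng.choice(choices)
    return out, 100.0 * (n - n_mut) / n


_COMP_CODE = {65: 84, 84: 65, 67: 71, 71: 67}


def _force_mismatch(arr: np.ndarray, pos: int, forbidden: int,
                    rng: np.random.Generator) -> None:
    """Set arr[pos] to a base other than ``forbidden`` (ASCII code)."""
    choices = _BASES[_BASES != forbidden]
    arr[pos] = rng.choice(choices)


def _break_direct_extensions(
    arr: np.ndarray, s1: int, s2: int, ln: int, rng: np.random.Generator
) -> None:
    """Make a planted direct pair maximal: the bases just outside each
    arm end must not extend the match (0-based arm starts)."""
    n = len(arr)
    if s1 - 1 >= 0 and s2 - 1 >= 0 and arr[s1 - 1] == arr[s2 - 1]:
        _force_mismatch(arr, s2 - 1, int(arr[s1 - 1]), rng)
    r1, r2 = s1 + ln, s2 + ln
    if r1 < n and r2 < n and arr[r1] == arr[r2]:
        _force_mismatch(arr, r2, int(arr[r1]), rng)


def _break_inverted_extensions(
    arr: np.ndarray, s1: int, e1: int, s2: int, e2: int,
    rng: np.random.Generator,
) -> None:
    """Make a planted inverted pair maximal (0-based inclusive arms)."""
    n = len(arr)
    if s1 - 1 >= 0 and e2 + 1 < n and arr[s1 - 1] == _COMP_CODE[int(arr[e2 + 1])]:
        _force_mismatch(arr, e2 + 1, int(arr[e2 + 1]), rng)
    if e1 + 1 < n and s2 - 1 >= 0 and arr[e1 + 1] == _COMP_CODE[int(arr[s2 - 1])]:
        _force_mismatch(arr, e1 + 1, int(arr[e1 + 1]), rng)


def _cds(start: int, length: int, product: str, tags: Sequence[str] = (),
         ftype: str = "CDS") -> FeatureRecord:
    return FeatureRecord(
        start=start,
        end=start + length - 1,
        strand="+",
        ftype=ftype,
        product=product,
        domain_tags=frozenset(tags),
    )


_FLAG_GENES: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "repA": [("replication initiator RepA", ("RepA",))],
    "relaxase": [("conjugative relaxase", ("Relaxase",))],
    "virD4": [("type IV coupling protein VirD4", ("VirD4",))],
    "virB4": [("conjugal transfer ATPase VirB4", ("VirB4",))],
    "tcpC": [("conjugal transfer protein TcpC (VirB8-like)", ("TcpC",))],
    "helicase": [("replicative DNA helicase (DnaB-like)", ("DnaB",))],
    "dna_polymerase": [("DNA polymerase I", ("PolI",))],
    "integrase": [("site-specific integrase", ("Integrase",))],
    "transposase": [("IS-family DDE transposase", ("Transposase",))],
    "toxin_antitoxin": [
        ("type II TA system toxin", ("Toxin",)),
        ("type II TA system antitoxin", ("Antitoxin",)),
    ],
}


def _place_backbone(
    flags: Sequence[str], cursor: int, features: list[FeatureRecord]
) -> int:
    """Append one gene (or gene pair) per flag starting at ``cursor``;
    returns the new cursor."""
    for flag in flags:
        if flag in ("t7ss", "trna_genes"):
            continue  # planted by dedicated machinery
        for product, tags in _FLAG_GENES[flag]:
            features.append(_cds(cursor, BACKBONE_GENE_LEN, product, tags))
            cursor += BACKBONE_GENE_LEN + BACKBONE_GENE_GAP
    return cursor


def _place_esx_cluster(
    signature: str,
    cursor: int,
    features: list[FeatureRecord],
    ecca_gap: int = ECCA_GAP,
) -> tuple[int, dict]:
    """Plant one ESX cluster following a "/"-joined gene-order signature
    ("-//-" inserts the distal-eccA gap); returns (new cursor, truth)."""
    tokens = [
        GAP_MARK if t == "\x00" else t
        for t in signature.replace(GAP_MARK, "\x00").split("/")
        if t
    ]
    start = cursor
    member_coords = []
    for tok in tokens:
        if tok == GAP_MARK:
            cursor += ecca_gap
            continue
        tag = GENE_TO_TAG[tok]
        features.append(
            _cds(cursor, ESX_GENE_LEN, f"ESX core component {tag}", (tag,))
        )
        member_coords.append({"gene": tok, "start": cursor,
                              "end": cursor + ESX_GENE_LEN - 1})
        cursor += ESX_GENE_LEN + ESX_GENE_GAP
    truth = {
        "signature": signature,
        "span_start": start,
        "span_end": member_coords[-1]["end"],
        "members": member_coords,
    }
    return cursor, truth


def generate_linear_plasmid(
    length: int,
    tir_len: int,
    tir_identity: float = 100.0,
    gc: float = 64.0,
    seed: int = 0,
    replicon_id: str = "synthetic_linear",
    backbone_flags: Sequence[str] = (),
    esx_signatures: Sequence[str] = (),
    internal_ir: Optional[tuple[int, float]] = None,
    n_trna: int = 0,
    max_tries: int = 20,
) -> tuple[AnnotatedReplicon, SyntheticTruth]:
    """Linear plasmid with terminal inverted repeats.

    ``internal_ir=(length, identity)`` additionally plants an internal
    inverted-repeat pair flanking a central region that carries the
    ``n_trna`` tRNA genes and a transposase at each flank — the
    tRNA-array architecture of large linear plasmids.
    """
    if 2 * tir_len >= length:
        raise ValueError("tir_len must be < length/2")
    rng = _rng(seed)
    for _ in range(max_tries):
        arr = _random_seq_array(rng, length, gc)
        arm = _random_seq_array(rng, tir_len, gc)
        arm2, exact_identity = _mutate_arm(rng, arm, tir_identity)
        rc2 = np.frombuffer(
            revcomp(arm2.tobytes().decode()).encode(), dtype=np.uint8
        )
        arr[:tir_len] = arm
        arr[length - tir_len :] = rc2
        _break_inverted_extensions(
            arr, 0, tir_len - 1, length - tir_len, length - 1, rng
        )
        planted = [(1, tir_len), (length - tir_len + 1, length)]
        truth = SyntheticTruth(
            seed=seed,
            replicon_id=replicon_id,
            topology="linear",
            tir={
                "arm1_start": 1,
                "arm1_end": tir_len,
                "arm2_start": length - tir_len + 1,
                "arm2_end": length,
                "length": tir_len,
                "identity": exact_identity,
            },
            backbone_flags=list(backbone_flags),
        )
        features: list[FeatureRecord] = []
        cursor = tir_len + 1000

        for sig in esx_signatures:
            cursor, esx_truth = _place_esx_cluster(sig, cursor, features)
            truth.esx_clusters.append(esx_truth)
            cursor += 8000  # keep planted clusters well separated

        if internal_ir is not None:
            ir_len, ir_identity = internal_ir
            ir1 = cursor
            region_len = max(3000, n_trna * 300 + 2000)
            ir2 = ir1 + ir_len + region_len
            ir_arm = _random_seq_array(rng, ir_len, gc)
            ir_arm2, ir_exact = _mutate_arm(rng, ir_arm, ir_identity)
            ir_rc = np.frombuffer(
                revcomp(ir_arm2.tobytes().decode()).encode(), dtype=np.uint8
            )
            arr[ir1 - 1 : ir1 - 1 + ir_len] = ir_arm
            arr[ir2 - 1 : ir2 - 1 + ir_len] = ir_rc
            _break_inverted_extensions(
                arr, ir1 - 1, ir1 + ir_len - 2, ir2 - 1, ir2 + ir_len - 2, rng
            )
            planted += [(ir1, ir1 + ir_len - 1), (ir2, ir2 + ir_len - 1)]
            truth.inverted_pairs.append(
                {
                    "arm1_start": ir1,
                    "arm1_end": ir1 + ir_len - 1,
                    "arm2_start": ir2,
                    "arm2_end": ir2 + ir_len - 1,
                    "length": ir_len,
                    "identity": ir_exact,
                }
            )
            features.append(
                _cds(ir1 + ir_len + 100, 900, "IS-family DDE transposase",
                     ("Transposase",))
            )
            t_cursor = ir1 + ir_len + 1200
            for i in range(n_trna):
                features.append(
                    _cds(t_cursor, 80, f"tRNA-{i}", ("tRNA",), ftype="tRNA")
                )
                t_cursor += 300
            features.append(
                _cds(ir2 - 1100, 900, "IS-family DDE transposase",
                     ("Transposase",))
            )
            cursor = ir2 + ir_len + 1000

        cursor = _place_backbone(backbone_flags, cursor, features)
        if cursor > length - tir_len:
            raise ValueError("planted content does not fit in length")

        seq = arr.tobytes().decode()
        if length > VERIFY_MAX_BP or _planted_regions_ok(
            seq, planted, VERIFY_MIN_LEN
        ):
            rep = AnnotatedReplicon(
                id=replicon_id, sequence=seq, features=features,
                source_path=f"synthetic:seed={seed}",
            )
            return rep, truth
    raise RuntimeError("could not generate a repeat-free background")


def generate_circular_plasmid(
    length: int,
    end_overlap: int,
    n_spanning_pairs: int = 0,
    noise_rate: float = 0.0,
    gc: float = 65.0,
    seed: int = 0,
    replicon_id: str = "synthetic_circular",
    backbone_flags: Sequence[str] = (),
    esx_signatures: Sequence[str] = (),
    end_window: int = 400,
    max_tries: int = 20,
) -> tuple[AnnotatedReplicon, list[ReadPairLink], SyntheticTruth]:
    """Circular plasmid linearized with a duplicated terminus.

    ``n_spanning_pairs`` read-pair links are planted across the two ends
    (left mate on "-", right mate on "+", within ``end_window`` of each
    end); each link is independently corrupted with probability
    ``noise_rate`` (one mate moved to a random internal position with a
    random orientation — a mispaired mate).
    """
    if end_overlap >= length / 10:
        raise ValueError("end_overlap must be < length/10")
    rng = _rng(seed)
    for _ in range(max_tries):
        core = _random_seq_array(rng, length - end_overlap, gc)
        arr = np.concatenate([core, core[:end_overlap]])
        planted = (
            [(1, end_overlap), (length - end_overlap + 1, length)]
            if end_overlap
            else []
        )
        features: list[FeatureRecord] = []
        cursor = max(end_overlap, 200) + 1000
        for sig in esx_signatures:
            cursor, _ = _place_esx_cluster(sig, cursor, features)
            cursor += 8000
        cursor = _place_backbone(backbone_flags, cursor, features)
        if cursor > length - end_overlap:
            raise ValueError("planted content does not fit in length")
        seq = arr.tobytes().decode()
        if length <= VERIFY_MAX_BP and not _planted_regions_ok(
            seq, planted, VERIFY_MIN_LEN
        ):
            continue

        links: list[ReadPairLink] = []
        n_clean = 0
        for i in range(n_spanning_pairs):
            pos1 = int(rng.integers(1, end_window + 1))
            pos2 = int(rng.integers(length - end_window + 1, length + 1))
            o1, o2 = "-", "+"
            if noise_rate > 0 and rng.random() < noise_rate:
                # mispair: throw one mate somewhere internal
                if rng.random() < 0.5:
                    pos1 = int(rng.integers(end_window + 1, length - end_window))
                    o1 = "+" if rng.random() < 0.5 else "-"
                else:
                    pos2 = int(rng.integers(end_window + 1, length - end_window))
                    o2 = "+" if rng.random() < 0.5 else "-"
            else:
                n_clean += 1
            links.append(
                ReadPairLink(f"pair{i:04d}", replicon_id, pos1, o1, pos2, o2)
            )
        truth = SyntheticTruth(
            seed=seed,
            replicon_id=replicon_id,
            topology="circular",
            end_overlap=end_overlap,
            backbone_flags=list(backbone_flags),
            links={
                "n_total": n_spanning_pairs,
                "n_clean_spanning": n_clean,
                "noise_rate": noise_rate,
            },
        )
        if end_overlap:
            truth.dr_pairs.append(
                {
                    "arm1_start": 1,
                    "arm1_end": end_overlap,
                    "arm2_start": length - end_overlap + 1,
                    "arm2_end": length,
                    "length": end_overlap,
                    "identity": 100.0,
                    "note": "duplicated terminus",
                }
            )
        rep = AnnotatedReplicon(
            id=replicon_id, sequence=seq, features=features,
            source_path=f"synthetic:seed={seed}",
        )
        return rep, links, truth
    raise RuntimeError("could not generate a repeat-free background")


def generate_ice(
    length: int = 100_000,
    dr_len: int = 167,
    cargo_span: int = 40_000,
    esx_signatures: Sequence[str] = (
        "eccE/eccB/eccD/eccC/eccD/mycP/-//-/eccA",
        "eccC/eccB/eccD/mycP/eccE/-//-/eccA",
    ),
    backbone_flags: Sequence[str] = (
        "relaxase", "virD4", "virB4", "tcpC", "helicase",
        "toxin_antitoxin", "transposase",
    ),
    second_dr_len: Optional[int] = None,
    end_overlap: int = 77,
    gc: float = 64.0,
    seed: int = 0,
    replicon_id: str = "synthetic_ice",
    max_tries: int = 20,
) -> tuple[AnnotatedReplicon, SyntheticTruth]:
    """ICE-like element in its excised (circularizable) form.

    Architecture: a direct-repeat pair of ``dr_len`` bp flanks a cargo
    region of ``cargo_span`` bp carrying the first ESX signature, with an
    IS transposase immediately outside the second arm; further ESX
    signatures and the backbone gene complement follow downstream,
    optionally bracketed by a second direct-repeat pair
    (``second_dr_len``).  A duplicated terminus of ``end_overlap`` bp
    makes the element circularizable.  Contradictory backbone flag sets
    (an ICE with repA, say) are generated exactly as requested and noted
    in the truth — classifier tests need contradictions too.
    """
    if cargo_span + 2 * dr_len >= length:
        raise ValueError("cargo_span + 2*dr_len must be < length")
    rng = _rng(seed)
    for _ in range(max_tries):
        core = _random_seq_array(rng, length - end_overlap, gc)
        arr = np.concatenate([core, core[:end_overlap]])
        planted: list[tuple[int, int]] = (
            [(1, end_overlap), (length - end_overlap + 1, length)]
            if end_overlap
            else []
        )
        features: list[FeatureRecord] = []
        truth = SyntheticTruth(
            seed=seed,
            replicon_id=replicon_id,
            topology="circular",
            end_overlap=end_overlap,
            backbone_flags=list(backbone_flags),
        )
        if "repA" in backbone_flags:
            truth.notes.append(
                "contradictory request: ICE architecture with repA"
            )

        def plant_dr(arm1_start: int, arm2_start: int, ln: int, label: str):
            arm = _random_seq_array(rng, ln, gc)
            arr[arm1_start - 1 : arm1_start - 1 + ln] = arm
            arr[arm2_start - 1 : arm2_start - 1 + ln] = arm
            _break_direct_extensions(arr, arm1_start - 1, arm2_start - 1, ln, rng)
            planted.append((arm1_start, arm1_start + ln - 1))
            planted.append((arm2_start, arm2_start + ln - 1))
            truth.dr_pairs.append(
                {
                    "arm1_start": arm1_start,
                    "arm1_end": arm1_start + ln - 1,
                    "arm2_start": arm2_start,
                    "arm2_end": arm2_start + ln - 1,
                    "length": ln,
                    "identity": 100.0,
                    "note": label,
                }
            )

        dr1_a1 = max(end_overlap + 200, 2000)
        dr1_a2 = dr1_a1 + dr_len + cargo_span
        plant_dr(dr1_a1, dr1_a2, dr_len, "DR flanking ESX cargo")

        cursor = dr1_a1 + dr_len + 1500
        if esx_signatures:
            cursor, esx_truth = _place_esx_cluster(
                esx_signatures[0], cursor, features
            )
            truth.esx_clusters.append(esx_truth)
            if esx_truth["span_end"] >= dr1_a2:
                raise ValueError("cargo_span too small for the ESX cluster")
        # filler cargo CDS so the delimited region is never gene-empty
        features.append(_cds(dr1_a2 - 2500, 1200, "hypothetical protein"))

        # IS transposase adjacent to (200 bp outside) the second DR arm
        is_start = dr1_a2 + dr_len + 200
        features.append(
            _cds(is_start, 1200, "IS110 family DDE transposase",
                 ("Transposase",))
        )
        truth.notes.append(f"IS transposase at {is_start} adjacent to DR arm2")

        cursor = is_start + 1200 + 2000
        dr2_a1 = None
        if second_dr_len:
            dr2_a1 = cursor
            cursor += second_dr_len + 500
        for sig in esx_signatures[1:]:
            cursor, esx_truth = _place_esx_cluster(sig, cursor, features)
            truth.esx_clusters.append(esx_truth)
            cursor += 3000
        cursor = _place_backbone(backbone_flags, cursor, features)
        if second_dr_len:
            dr2_a2 = cursor + 500
            plant_dr(dr2_a1, dr2_a2, second_dr_len, "DR flanking conjugation module")
            cursor = dr2_a2 + second_dr_len + 500
        if cursor > length - max(end_overlap, 500):
            raise ValueError("planted content does not fit in length")

        seq = arr.tobytes().decode()
        if length <= VERIFY_MAX_BP and not _planted_regions_ok(
            seq, planted, VERIFY_MIN_LEN
        ):
            continue
        rep = AnnotatedReplicon(
            id=replicon_id, sequence=seq, features=features,
            source_path=f"synthetic:seed={seed}",
        )
        return rep, truth
    raise RuntimeError("could not generate a repeat-free background")


def generate_shared_pair(
    len_a: int,
    len_b: int,
    segments: Sequence[tuple[int, int, int, float, str]],
    gc: float = 64.0,
    seed: int = 0,
) -> tuple[str, str, SyntheticTruth]:
    """Two sequences with planted shared segments.

    ``segments`` entries are (a_start, b_start, length, identity,
    strand), 1-based; the A region is copied into B with the stated
    substitution load (exact resulting identity recorded in truth).
    """
    rng = _rng(seed)
    a = _random_seq_array(rng, len_a, gc)
    b = _random_seq_array(rng, len_b, gc)
    truth = SyntheticTruth(
        seed=seed, replicon_id="synthetic_pair", topology="n/a"
    )
    for a_start, b_start, ln, identity, strand in segments:
        if a_start + ln - 1 > len_a or b_start + ln - 1 > len_b:
            raise ValueError("planted segment outside sequence bounds")
        region = a[a_start - 1 : a_start - 1 + ln]
        mutated, exact = _mutate_arm(rng, region, identity)
        if strand == "-":
            mutated = np.frombuffer(
                revcomp(mutated.tobytes().decode()).encode(), dtype=np.uint8
            )
        b[b_start - 1 : b_start - 1 + ln] = mutated
        truth.shared_segments.append(
            {
                "a_start": a_start,
                "a_end": a_start + ln - 1,
                "b_start": b_start,
                "b_end": b_start + ln - 1,
                "length": ln,
                "identity": exact,
                "strand": strand,
            }
        )
    return a.tobytes().decode(), b.tobytes().decode(), truth


# ---------------------------------------------------------------------------
# Study-condition fixture suite

#: Feature-flag complements of the four element archetypes the package
#: is designed around (one column each of the report matrix).
TABLE_ARCHETYPES: dict[str, dict] = {
    "linear_megaplasmid": {
        "topology": "linear",
        "flags": ["virB4", "helicase", "dna_polymerase", "integrase",
                  "transposase", "trna_genes", "t7ss", "toxin_antitoxin"],
        "classification": "cryptic_plasmid",
    },
    "conjugative_plasmid": {
        "topology": "circular",
        "flags": ["repA", "relaxase", "virD4", "virB4", "tcpC",
                  "transposase", "t7ss", "toxin_antitoxin"],
        "classification": "conjugative_plasmid",
    },
    "cryptic_plasmid": {
        "topology": "linear",
        "flags": ["repA"],
        "classification": "cryptic_plasmid",
    },
    "ice": {
        "topology": "circular",
        "flags": ["relaxase", "virD4", "virB4", "tcpC", "helicase",
                  "transposase", "t7ss", "toxin_antitoxin"],
        "classification": "putative_ICE",
    },
}


def generate_table_suite(seed: int = 0):
    """The four archetype fixtures at test scale.

    Returns a dict name -> (replicon, links, truth); links is an empty
    list for the linear fixtures.
    """
    out = {}
    rep, truth = generate_linear_plasmid(
        length=48_000,
        tir_len=145,
        gc=62.0,
        seed=seed + 1,
        replicon_id="linear_megaplasmid",
        backbone_flags=[
            f for f in TABLE_ARCHETYPES["linear_megaplasmid"]["flags"]
            if f not in ("t7ss", "trna_genes")
        ],
        esx_signatures=("eccA/eccB/eccC/eccD/mycP/eccE",),
        internal_ir=(101, 99.0),
        n_trna=8,
    )
    out["linear_megaplasmid"] = (rep, [], truth)

    rep, links, truth = generate_circular_plasmid(
        length=62_000,
        end_overlap=77,
        n_spanning_pairs=30,
        gc=65.0,
        seed=seed + 2,
        replicon_id="conjugative_plasmid",
        backbone_flags=[
            f for f in TABLE_ARCHETYPES["conjugative_plasmid"]["flags"]
            if f != "t7ss"
        ],
        esx_signatures=("eccC/eccB/eccD/mycP/eccE/-//-/eccA",),
    )
    out["conjugative_plasmid"] = (rep, links, truth)

    rep, truth = generate_linear_plasmid(
        length=21_616,
        tir_len=489,
        gc=64.0,
        seed=seed + 3,
        replicon_id="cryptic_plasmid",
        backbone_flags=["repA"],
    )
    out["cryptic_plasmid"] = (rep, [], truth)

    rep, truth = generate_ice(
        length=100_000,
        dr_len=167,
        cargo_span=40_000,
        second_dr_len=648,
        gc=64.0,
        seed=seed + 4,
        replicon_id="ice",
    )
    # ICE circularity below rides on the duplicated terminus alone unless
    # the caller supplies links; plant a spanning-link set for it too
    n = len(rep)
    rng = _rng(seed + 5)
    links = [
        ReadPairLink(
            f"ice_pair{i:03d}", rep.id,
            int(rng.integers(1, 401)), "-",
            int(rng.integers(n - 400 + 1, n + 1)), "+",
        )
        for i in range(10)
    ]
    truth.links = {"n_total": 10, "n_clean_spanning": 10, "noise_rate": 0.0}
    out["ice"] = (rep, links, truth)
    return out
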