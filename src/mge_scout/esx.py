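"""ESX (type VII secretion system) locus calling and signature typing.

Mycobacterial T7SS loci are clusters of the six core components EccA,
EccB, EccC, EccD, EccE and MycP.  A locus is called when at least
``min_core`` core-tagged genes sit close together (single-linkage
clustering along the replicon); eccA frequently lies well downstream of
the rest of the cluster, so a lone distal eccA within ``eccA_reach`` of a
called cluster is appended to it, separated in the gene-order signature
by the "-//-" gap marker.

Typing is by gene-order signature: the locus token sequence is compared
against a small editable reference table with token-level edit distance
(both reading directions, since locus orientation in a contig is
arbitrary); the nearest reference wins, with ties or distances above a
threshold left untyped.  Duplicated core genes are kept as distinct
tokens — the double eccD is exactly what distinguishes ESX-4-bis from
ESX-4.
"""
from __future__ import annotations

import logging
from typing import Optional

from .records import AnnotatedReplicon, EsxLocus
from .vocab import (
    ESX_CORE_TAGS,
    ESX_REFERENCE_SIGNATURES,
    GAP_MARK,
    TAG_TO_GENE,
)

logger = logging.getLogger(__name__)

_CORE = frozenset(ESX_CORE_TAGS)


def _core_tag(feature) -> Optional[str]:
    hits = feature.domain_tags & _CORE
    if len(hits) > 1:
        logger.warning(
            "feature %d..%d carries multiple ESX core tags %s; using %s",
            feature.start, feature.end, sorted(hits), sorted(hits)[0],
        )
    return sorted(hits)[0] if hits else None


def call_esx_loci(
    replicon: AnnotatedReplicon,
    max_gap: int = 6000,
    min_core: int = 4,
    eccA_reach: int = 20000,
) -> list[EsxLocus]:
    """Call T7SS loci from domain-tagged annotations.

    Parameters
    ----------
    max_gap:
        Largest inter-gene gap (bp, end to next start) linking two core
        genes into the same cluster.
    min_core:
        Minimum core genes per reported locus.
    eccA_reach:
        Distance (bp) within which a lone distal eccA is appended to the
        nearest called cluster, with a "-//-" marker in the signature.
    """
    cores = [
        (idx, tag, feat)
        for idx, feat in enumerate(replicon.features)
        if (tag := _core_tag(feat)) is not None
    ]
    if not cores:
        return []

    # single-linkage clustering along the replicon
    clusters: list[list[tuple[int, str, object]]] = [[cores[0]]]
    for item in cores[1:]:
        prev_feat = clusters[-1][-1][2]
        gap = item[2].start - prev_feat.end - 1
        if gap <= max_gap:
            clusters[-1].append(item)
        else:
            clusters.append([item])

    called = [c for c in clusters if len(c) >= min_core]
    leftovers = [
        item for c in clusters if len(c) < min_core for item in c
    ]

    loci: list[EsxLocus] = []
    used_distal: set[int] = set()
    for cluster in called:
        members = [(idx, TAG_TO_GENE[tag]) for idx, tag, _ in cluster]
        span_start = cluster[0][2].start
        span_end = cluster[-1][2].end
        tokens = [g for _, g in members]

        # attach the nearest unused distal eccA within reach, either side
        best: Optional[tuple[int, int, object]] = None  # (dist, idx, feat)
        for idx, tag, feat in leftovers:
            if tag != "EccA" or idx in used_distal:
                continue
            if feat.start > span_end:
                dist = feat.start - span_end - 1
            elif feat.end < span_start:
                dist = span_start - feat.end - 1
            else:
                continue
            if dist <= eccA_reach and (best is None or dist < best[0]):
                best = (dist, idx, feat)
        if best is not None:
            _, idx, feat = best
            used_distal.add(idx)
            if feat.start > span_end:
                members.append((idx, "eccA"))
                tokens = tokens + [GAP_MARK, "eccA"]
                span_end = feat.end
            else:
                members.insert(0, (idx, "eccA"))
                tokens = ["eccA", GAP_MARK] + tokens
                span_start = feat.start

        loci.append(
            EsxLocus(
                replicon_id=replicon.id,
                members=members,
                span_start=span_start,
                span_end=span_end,
                n_core=len(members),
                signature="/".join(tokens),
            )
        )

    loci.sort(key=lambda l: l.span_start)
    logger.info(
        "%s: %d ESX locus(es) from %d core-tagged genes",
        replicon.id, len(loci), len(cores),
    )
    return loci


def _edit_distance(a: list[str], b: list[str]) -> int:
    """Levenshtein distance over token sequences."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def _split_signature(signature: str) -> list[str]:
    # "-//-" contains "/" so it cannot survive a naive split; protect it
    return [
        GAP_MARK if t == "\x00" else t
        for t in signature.replace(GAP_MARK, "\x00").split("/")
        if t != ""
    ]


def classify_esx_type(
    locus: EsxLocus,
    reference_signatures: Optional[dict[str, str]] = None,
    max_distance: int = 2,
) -> str:
    """Assign an ESX type by nearest reference gene-order signature.

    Token-level edit distance, evaluated in both reading directions of
    the locus; ties between different types, or a best distance above
    ``max_distance``, return "untyped".
    """
    refs = reference_signatures or ESX_REFERENCE_SIGNATURES
    query = _split_signature(locus.signature)
    if not query:
        return "untyped"
    scored: list[tuple[int, str]] = []
    for name, ref_sig in refs.items():
        ref = _split_signature(ref_sig)
        d = min(
            _edit_distance(query, ref),
            _edit_distance(query[::-1], ref),
        )
        scored.append((d, name))
    scored.sort()
    best_d, best_name = scored[0]
    if best_d > max_distance:
        return "untyped"
    if len(scored) > 1 and scored[1][0] == best_d and scored[1][1] != best_name:
        return "untyped"
    return best_name


def type_esx_loci(
    loci: list[EsxLocus],
    reference_signatures: Optional[dict[str, str]] = None,
    max_distance: int = 2,
) -> list[EsxLocus]:
    """Assign types in place and return the loci."""
    for locus in loci:
        locus.assigned_type = classify_esx_type(
            locus, reference_signatures, max_distance
        )
    return loci
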