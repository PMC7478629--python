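"""Per-replicon summary statistics: length, GC content, feature counts."""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import AnnotatedReplicon

logger = logging.getLogger(__name__)


class UndefinedGCError(ValueError):
    """GC content is undefined for an empty or all-N sequence."""


@dataclass
class ReplistatRecord:
    replicon_id: str
    length_bp: int
    gc_percent: float
    n_cds: int
    n_trna: int


def gc_content(sequence: str) -> float:
    """GC percentage over unambiguous bases.

    N (and any non-ACGT character) is excluded from both numerator and
    denominator.  Raises :class:`UndefinedGCError` for sequences with no
    unambiguous base — a distinct signal, not 0.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedGCError("no unambiguous bases; GC content undefined")
    return 100.0 * gc / (gc + at)


def round_percent(value: float) -> int:
    """Half-up rounding to integer percent for report display."""
    return int(value + 0.5)


def count_features(replicon: AnnotatedReplicon, ftype: str) -> int:
    """Count features of one type (CDS, tRNA, other)."""
    if ftype not in ("CDS", "tRNA", "other"):
        logger.warning("unknown feature type %r; count is 0", ftype)
        return 0
    return sum(1 for f in replicon.features if f.ftype == ftype)


def replicon_stats(replicon: AnnotatedReplicon) -> ReplistatRecord:
    return ReplistatRecord(
        replicon_id=replicon.id,
        length_bp=len(replicon),
        gc_percent=gc_content(replicon.sequence),
        n_cds=count_features(replicon, "CDS"),
        n_trna=count_features(replicon, "tRNA"),
    )
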