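"""Small sequence helpers shared across modules."""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_sequence(seq: str) -> str:
    """Uppercase and map anything outside {A,C,G,T} to N."""
    s = seq.upper()
    if set(s) <= VALID_BASES:
        return s
    return "".join(c if c in VALID_BASES else "N" for c in s)


def seq_to_array(seq: str) -> np.ndarray:
    """Sequence as a uint8 code array; N and friends get code 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for code, base in enumerate(b"ACGT"):
        out[arr == base] = code
    return out


def comp_array(codes: np.ndarray) -> np.ndarray:
    """Complement of a code array (A<->T, C<->G); N (4) stays 4."""
    out = codes.copy()
    mask = codes < 4
    out[mask] = 3 - codes[mask]
    return out
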