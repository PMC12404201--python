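"""Small shared helpers: alphabet ops, rounding, RNG stream derivation."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: nucleotide order used by every array-coded routine
ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3; any other symbol (e.g. N) as 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for i, c in enumerate(ALPHABET):
        arr[b == ord(c)] = i
    return arr


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties toward +inf."""
    return int(np.floor(x + 0.5))


def child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent generator for a named sub-stream.

    A fixed integer offset per stage keeps stages statistically independent
    while the whole simulation remains a pure function of one seed.
    """
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])
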