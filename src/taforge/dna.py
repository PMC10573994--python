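"""Low-level DNA sequence helpers shared across the package.

Sequences are plain Python strings over the alphabet {A, C, G, T}; hot paths
work on numpy uint8 code arrays (A=0, C=1, G=2, T=3).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

A, C, G, T = 0, 1, 2, 3


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (A=0, C=1, G=2, T=3)."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        bad = set(seq) - set("ACGTacgt")
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings (brute force)."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def ta_positions(codes: np.ndarray) -> np.ndarray:
    """0-based start offsets of every (overlapping) TA dinucleotide."""
    if len(codes) < 2:
        return np.empty(0, dtype=np.int64)
    return np.nonzero((codes[:-1] == T) & (codes[1:] == A))[0].astype(np.int64)


def count_ta(seq: str) -> int:
    return int(len(ta_positions(encode(seq))))
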