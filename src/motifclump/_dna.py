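"""Shared DNA alphabet helpers: integer encoding and strand symmetry maps."""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
A, C, G, T = range(4)
COMPLEMENT = np.array([T, G, C, A], dtype=np.int8)

# byte -> code lookup; non-ACGT maps to -1
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(ALPHABET):
    _LUT[ord(_ch)] = _i
    _LUT[ord(_ch.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A,C,G,T -> 0..3; other -> -1)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp_str(word: str) -> str:
    return decode(COMPLEMENT[encode(word)][::-1])


def kmer_index(codes: np.ndarray) -> int:
    """Base-4 integer for a short k-mer given as codes (empty -> 0)."""
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def index_to_codes(idx: int, k: int) -> np.ndarray:
    out = np.empty(k, dtype=np.int8)
    for j in range(k - 1, -1, -1):
        out[j] = idx % 4
        idx //= 4
    return out


def kmer_word(idx: int, k: int) -> str:
    return decode(index_to_codes(idx, k))
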