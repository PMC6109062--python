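"""Codon tables and fast sequence encoding shared across the pipeline."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}
STOP_INDICES = frozenset(CODON_INDEX[c] for c in STOP_CODONS)
SENSE_INDICES = np.array([CODON_INDEX[c] for c in SENSE_CODONS], dtype=np.int64)

# base -> 2-bit code; anything else (N, ...) -> 255
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, other=255)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codons_at(encoded: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Codon indices (0..63) at the given start positions; -1 where any base is
    not in {A,C,G,T}. Positions must satisfy start+3 <= len(encoded)."""
    b0 = encoded[starts].astype(np.int64)
    b1 = encoded[starts + 1].astype(np.int64)
    b2 = encoded[starts + 2].astype(np.int64)
    idx = 16 * b0 + 4 * b1 + b2
    idx[(b0 > 3) | (b1 > 3) | (b2 > 3)] = -1
    return idx
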