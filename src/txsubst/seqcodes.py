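"""Shared nucleotide/trinucleotide integer encodings.

Bases are encoded A=0, C=1, G=2, T=3 so that complementation is ``3 - b``.
A trinucleotide (a, b, c) is encoded as ``16*a + 4*b + c`` (0..63).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
N_TRIPLETS = 64

BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    BASE_TO_CODE[ord(_b)] = _i
    BASE_TO_CODE[ord(_b.lower())] = _i

COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)

# revcomp of triplet code: (a,b,c) -> (c',b',a')
TRIPLET_REVCOMP = np.empty(64, dtype=np.int64)
for _a in range(4):
    for _b in range(4):
        for _c in range(4):
            TRIPLET_REVCOMP[16 * _a + 4 * _b + _c] = (
                16 * (3 - _c) + 4 * (3 - _b) + (3 - _a)
            )


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT(N) string to uint8 codes; N/other -> 255."""
    return BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    out = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    return out.tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


def triplet_code(tri: str) -> int:
    a, b, c = (BASES.index(x) for x in tri.upper())
    return 16 * a + 4 * b + c


def triplet_str(code: int) -> str:
    return BASES[code >> 4] + BASES[(code >> 2) & 3] + BASES[code & 3]
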