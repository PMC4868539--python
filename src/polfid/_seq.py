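"""Base-level encodings shared across modules.

Bases are coded A=0, C=1, G=2, T=3; anything else (including N) is 4 and
never counts as a match or a mismatch.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    CODE[ord(_b)] = _i
    CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement in code space: A<->T, C<->G, N->N
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    return CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into an ACGTN string."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMP_TABLE)[::-1]


def is_transition(ref_code: int, alt_code: int) -> bool:
    return TRANSITION.get(int(ref_code)) == int(alt_code)
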