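"""Low-level nucleotide utilities.

Sequences travel in two representations: Python ``str`` over the alphabet
``ACGT`` for I/O and bookkeeping, and numpy ``uint8`` code arrays
(A=0, C=1, G=2, T=3) for bulk simulation and alignment arithmetic.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array."""
    codes = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains characters outside ACGT")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    # complement of code c is 3 - c under the A/C/G/T encoding
    return (3 - codes)[::-1]


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def mutate_codes(
    rng: np.random.Generator, codes: np.ndarray, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Substitute bases independently at the given per-base rate.

    Returns the mutated copy and the (sorted) positions that changed.  A
    substitution is always to a *different* base: the new code is
    ``(old + shift) % 4`` with ``shift`` uniform on {1, 2, 3}.
    """
    out = codes.copy()
    if rate <= 0 or codes.size == 0:
        return out, np.empty(0, dtype=np.int64)
    mask = rng.random(codes.size) < rate
    pos = np.flatnonzero(mask)
    if pos.size:
        shift = rng.integers(1, 4, size=pos.size, dtype=np.uint8)
        out[pos] = (out[pos] + shift) % 4
    return out, pos


def apply_errors(
    rng: np.random.Generator, mat: np.ndarray, rate: float
) -> np.ndarray:
    """Apply independent substitution errors to a (reads x length) code matrix."""
    if rate <= 0 or mat.size == 0:
        return mat
    mask = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    mat[mask] = (mat[mask] + shift[mask]) % 4
    return mat
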