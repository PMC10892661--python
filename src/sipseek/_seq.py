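"""Internal helpers for fixed-length DNA handled as uint8 code matrices.

Bases are encoded A=0, C=1, G=2, T=3.  All synthetic amplicons share one
length, so a read set is a dense ``(n_reads, length)`` uint8 array, which the
generators and the k-mer classifier exchange directly without string
round-trips.
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


def encode(seqs) -> np.ndarray:
    """Encode equal-length DNA strings into a (n, L) uint8 matrix."""
    if isinstance(seqs, str):
        seqs = [seqs]
    n = len(seqs)
    if n == 0:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    if raw.size != n * length:
        raise ValueError("sequences must all have the same length")
    codes = _CODE[raw.reshape(n, length)]
    if (codes == 255).any():
        raise ValueError("sequences may only contain A, C, G, T")
    return codes


def decode(codes: np.ndarray) -> list[str]:
    """Decode a (n, L) uint8 matrix back into DNA strings."""
    ascii_mat = _BASES[np.asarray(codes, dtype=np.uint8)]
    return [row.tobytes().decode("ascii") for row in ascii_mat]


def mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions at the given per-site rate.

    A substituted site changes to one of the three other bases, uniformly.
    Returns a new matrix; the input is not modified.
    """
    out = np.array(codes, dtype=np.uint8, copy=True)
    if rate <= 0:
        return out
    hit = rng.random(out.shape) < rate
    # adding 1..3 modulo 4 always yields a different base
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out
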