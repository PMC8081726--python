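"""Vectorized canonical k-mer extraction on 2-bit-packed uint64 codes.

k-mers (k <= 32) are encoded A=0, C=1, G=2, T=3 into uint64; the canonical
form is the numeric minimum of a window's forward and reverse-complement
codes, so strand never matters.  Windows containing non-ACGT characters are
dropped.  All operations are plain numpy passes, fast enough for tens of
megabases.
"""

from __future__ import annotations

import numpy as np

__all__ = ["canonical_kmers", "decode_kmer"]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_BASES = "ACGT"


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """All canonical k-mer codes of ``seq``, one per valid window, in
    order.  Windows touching non-ACGT characters are omitted."""
    if not (1 <= k <= 32):
        raise ValueError("k must be in [1, 32]")
    codes = _encode(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    valid = codes != 255
    codes64 = codes.astype(np.uint64)
    comp64 = (np.uint64(3) - codes64) & np.uint64(3)

    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    ok = np.ones(n, dtype=bool)
    for t in range(k):
        window = slice(t, t + n)
        fwd |= codes64[window] << np.uint64(2 * (k - 1 - t))
        # reverse complement: base at offset t maps to position t from the top
        rev |= comp64[window] << np.uint64(2 * t)
        ok &= valid[window]
    out = np.minimum(fwd, rev)
    return out[ok]


def decode_kmer(code: int, k: int) -> str:
    """Inverse of the forward encoding, for reporting small marker sets."""
    return "".join(_BASES[(int(code) >> (2 * (k - 1 - t))) & 3] for t in range(k))
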