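"""64-bit rolling-hash identity for fixed-length DNA words.

Every k-mer is identified by the positional polynomial hash

    h(x) = sum_i code(x[i]) * B**(k-1-i)  (mod 2**64)

with a fixed odd multiplier B, so the hash of a suffix/prefix neighbor, of a
reverse complement, or of the joining (k+1)-mer can be derived from the hash of
the current word in O(1) — the update rules the de Bruijn traversals rely on.
Bases map to codes 1..4 (A<C<G<T); 0 marks anything outside the alphabet
(N, read separators) and invalidates every window covering it.

B is odd hence invertible mod 2**64, which gives exact prefix-side updates.
Hash collisions are possible in principle but at desk scale (<=1e8 distinct
words against a 64-bit space) the expected number of colliding pairs is <1e-3.
"""

from __future__ import annotations

import numpy as np

BASE = 0x9E3779B97F4A7C15
BASE_INV = pow(BASE, -1, 1 << 64)
M64 = (1 << 64) - 1

_BASE_U = np.uint64(BASE)
_BASE_INV_U = np.uint64(BASE_INV)

_CODE = np.zeros(256, dtype=np.uint8)
for _b, _c in zip(b"ACGT", (1, 2, 3, 4)):
    _CODE[_b] = _c
    _CODE[_b + 32] = _c  # lowercase

CODE_TO_BASE = "?ACGT"


def encode(seq: str | bytes) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 1..4; anything else -> 0)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def rc_codes(codes: np.ndarray) -> np.ndarray:
    """Complement codes in place order (1<->4, 2<->3); invalid stays invalid."""
    out = (np.uint8(5) - codes).astype(np.uint8)
    out[codes == 0] = 0
    return out


def pow_base(e: int) -> int:
    return pow(BASE, e, 1 << 64)


def window_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Hashes of all length-k windows of ``codes`` (vectorized Horner scheme)."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n - k + 1, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            h *= _BASE_U
            h += codes[j : n - k + 1 + j]
    return h


def window_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of windows containing no invalid (code 0) position."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=bool)
    bad = np.concatenate(([0], np.cumsum(codes == 0)))
    return (bad[k:] - bad[:-k]) == 0


def paired_window_hashes(codes: np.ndarray, k: int):
    """(forward hash, reverse-complement hash, valid) for every window.

    Entry i of each array refers to the window ``codes[i:i+k]``.
    """
    hf = window_hashes(codes, k)
    hr = window_hashes(rc_codes(codes)[::-1], k)[::-1]
    return hf, hr, window_valid(codes, k)


def hash_str(s: str) -> int | None:
    """Scalar hash of a DNA string; None if it contains a non-ACGT character."""
    h = 0
    for b in s.encode("ascii"):
        c = _CODE[b]
        if c == 0:
            return None
        h = (h * BASE + int(c)) & M64
    return h


class CountTable:
    """Sorted hash -> occurrence-count table for one word length."""

    __slots__ = ("hashes", "counts")

    def __init__(self, hashes: np.ndarray, counts: np.ndarray):
        self.hashes = hashes
        self.counts = counts

    @classmethod
    def from_occurrences(cls, h: np.ndarray) -> "CountTable":
        u, c = np.unique(h, return_counts=True)
        return cls(u.astype(np.uint64), c.astype(np.int64))

    def lookup_many(self, q: np.ndarray) -> np.ndarray:
        """Counts for an array of query hashes (0 where absent)."""
        q = np.ascontiguousarray(q, dtype=np.uint64)
        if self.hashes.size == 0:
            return np.zeros(q.shape, dtype=np.int64)
        idx = np.searchsorted(self.hashes, q)
        idx = np.minimum(idx, self.hashes.size - 1)
        hit = self.hashes[idx] == q
        return np.where(hit, self.counts[idx], 0)

    def lookup(self, h: int) -> int:
        i = int(np.searchsorted(self.hashes, np.uint64(h)))
        if i < self.hashes.size and int(self.hashes[i]) == h:
            return int(self.counts[i])
        return 0
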