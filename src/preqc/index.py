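"""Strand-aware k-mer counting index over a read collection.

This provides the query contract of a full-text index of the reads —
substring counting, random read extraction and implicit de Bruijn neighbor
queries — as exact hash-count tables for a declared set of k values. Counts
are strand-specific as observed in the reads: ``count(P)`` is the number of
occurrences of P literally, and ``count_rc(P) = count(P) + count(rc(P))``.
K-mers containing N (or any non-ACGT character) are never counted.

A k-mer and its reverse complement are one de Bruijn vertex; neighbor queries
report, for each of the four possible extensions, whether the neighbor exists
(count_rc > 0) and whether it is *strand-validated* — seen at least once on
each sequencing strand — which is the edge-validity rule used to suppress
branches induced by strand-specific systematic errors.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import _hashing as H
from .seqio import Read, ReadSet, reverse_complement


class KmerIndex:
    """Exact occurrence counts for fixed k values plus a verbatim read store."""

    def __init__(self, reads: ReadSet, k_values: Iterable[int]):
        ks = sorted(set(int(k) for k in k_values))
        if not ks:
            raise ValueError("k_values must be non-empty")
        if any(k <= 0 for k in ks):
            raise ValueError("k values must be positive")
        if len(reads) == 0:
            raise ValueError("cannot index an empty ReadSet")
        if min(ks) > reads.max_read_length:
            raise ValueError(
                f"k={min(ks)} is larger than every read "
                f"(max read length {reads.max_read_length})"
            )
        self.reads = reads
        self.k_values = tuple(ks)
        self.n_reads = len(reads)
        self.modal_read_length = reads.modal_read_length

        parts = []
        starts = np.empty(len(reads) + 1, dtype=np.int64)
        pos = 0
        for i, r in enumerate(reads):
            starts[i] = pos
            parts.append(H.encode(r.seq))
            parts.append(np.zeros(1, dtype=np.uint8))  # separator
            pos += len(r.seq) + 1
        starts[-1] = pos
        self._codes = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self._starts = starts
        self._tables: dict[int, H.CountTable] = {}
        for k in ks:
            hf = H.window_hashes(self._codes, k)
            valid = H.window_valid(self._codes, k)
            self._tables[k] = H.CountTable.from_occurrences(hf[valid])

    # -- counting ----------------------------------------------------------

    def _table(self, k: int) -> H.CountTable:
        try:
            return self._tables[k]
        except KeyError:
            raise ValueError(
                f"length {k} not indexed; available k values: {self.k_values}"
            ) from None

    def count(self, p: str) -> int:
        """Occurrences of pattern ``p`` on its literal strand."""
        if not p:
            raise ValueError("empty pattern")
        table = self._table(len(p))
        h = H.hash_str(p)
        return 0 if h is None else table.lookup(h)

    def count_rc(self, p: str) -> int:
        """Occurrences of ``p`` plus occurrences of its reverse complement."""
        return self.count(p) + self.count(reverse_complement(p))

    # -- read store --------------------------------------------------------

    def extract_read(self, i: int) -> Read:
        if not 0 <= i < self.n_reads:
            raise IndexError(f"read index {i} out of range [0, {self.n_reads})")
        return self.reads[i]

    def sample_read(self, rng: np.random.Generator) -> Read:
        return self.reads[int(rng.integers(0, self.n_reads))]

    def sample_read_indices(
        self, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        """n distinct read indices; all reads once when n >= n_reads."""
        if n >= self.n_reads:
            return np.arange(self.n_reads)
        return rng.choice(self.n_reads, size=n, replace=False)

    # -- de Bruijn neighbor queries ---------------------------------------

    def neighbors(self, x: str, side: str = "suffix") -> list[tuple[str, bool]]:
        """Existing neighbors of vertex ``x`` with strand-validation flags.

        Suffix neighbors are the k-mers Z+b (x = aZ) with count_rc > 0, in
        fixed base order A<C<G<T; a neighbor is strand-validated when it is
        seen at least once on each strand separately.
        """
        if side not in ("suffix", "prefix"):
            raise ValueError("side must be 'suffix' or 'prefix'")
        self._table(len(x))  # raises for unindexed length
        out = []
        for b in "ACGT":
            nb = x[1:] + b if side == "suffix" else b + x[:-1]
            fwd = self.count(nb)
            rev = self.count(reverse_complement(nb))
            if fwd + rev > 0:
                out.append((nb, fwd > 0 and rev > 0))
        return out

    def is_suffix_branch(self, x: str) -> bool:
        """True iff ``x`` has at least two strand-validated suffix neighbors."""
        return sum(1 for _, ok in self.neighbors(x, "suffix") if ok) >= 2

    # -- vectorized internals used by the samplers ------------------------

    def selected_codes(self, read_indices: np.ndarray) -> np.ndarray:
        """Concatenated codes (with separators) of the selected reads."""
        pieces = [
            self._codes[self._starts[i] : self._starts[i + 1]]
            for i in np.asarray(read_indices)
        ]
        return np.concatenate(pieces) if pieces else np.empty(0, np.uint8)

    def window_count_rc(self, codes: np.ndarray, k: int):
        """(count_rc, hf, hr, valid, first_code) for all windows of ``codes``."""
        table = self._table(k)
        hf, hr, valid = H.paired_window_hashes(codes, k)
        crc = table.lookup_many(hf) + table.lookup_many(hr)
        return crc, hf, hr, valid, codes[: hf.size]


def build_index(reads: ReadSet, k_values: Iterable[int]) -> KmerIndex:
    """Build a KmerIndex over the reads for the given k values."""
    return KmerIndex(reads, k_values)
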