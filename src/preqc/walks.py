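"""Greedy de Bruijn walks: fragment-size estimation and simulated assembly.

Fragment sizes: starting from the first k-mer of read X (default k = 51),
extend greedily to the highest-coverage strand-validated suffix neighbor
until the first k-mer of the reverse complement of mate Y is reached (mates
are assumed forward/reverse), there is no extension, or 1500 steps pass. On
success, the fragment size is the number of edges walked plus the mate
length (the span from X's start to Y's far end on the source molecule).

Simulated assembly: contigs start at the first k-mer of sampled reads whose
homozygous posterior is at least 0.5 and extend in both directions through
branches classified as errors or variants, stopping at repeat branches, dead
ends, in-walk revisits or the 50 000-k-mer cap. Visited k-mers go into a
Bloom filter so no region seeds two walks; contig length is the number of
k-mers visited, summarized as N50 per k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _hashing as H
from .branches import ClassifierParams, _classify_arrays
from .count_model import CountMixtureModel, fit_mixture_em, sample_count_histogram
from .index import KmerIndex
from .seqio import reverse_complement

logger = logging.getLogger(__name__)

FRAGMENT_WALK_K = 51
FRAGMENT_MAX_STEPS = 1500
ASSEMBLY_MAX_LEN = 50_000


def n50(lengths) -> int:
    """Largest L such that contigs of length >= L sum to half the total."""
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if arr.size == 0:
        return 0
    if np.any(arr <= 0):
        raise ValueError("contig lengths must be positive")
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, csum[-1] / 2.0)])


class BloomFilter:
    """Fixed-size Bloom filter over 64-bit hashes (3 probes).

    Sized at ~16 bits per expected item, giving a false-positive rate well
    under 1% at capacity. Only used to skip walk starts, never to decide a
    walk's own termination.
    """

    _MIX = 0xFF51AFD7ED558CCD

    def __init__(self, capacity: int):
        nbits = max(1024, 16 * capacity)
        self._nbits = nbits
        self._bits = np.zeros((nbits + 63) // 64, dtype=np.uint64)

    def _probes(self, h: int):
        h2 = (h * self._MIX) & H.M64 | 1
        for i in range(3):
            yield ((h + i * h2) & H.M64) % self._nbits

    def add(self, h: int) -> None:
        for p in self._probes(h):
            self._bits[p >> 6] |= np.uint64(1 << (p & 63))

    def __contains__(self, h: int) -> bool:
        return all(
            self._bits[p >> 6] >> np.uint64(p & 63) & np.uint64(1)
            for p in self._probes(h)
        )


class _Cursor:
    """Current k-mer of a walk, with O(1) hash updates on extension."""

    __slots__ = ("k", "codes", "hf", "hr", "_powk1")

    def __init__(self, codes: np.ndarray, k: int):
        if codes.size != k or (codes == 0).any():
            raise ValueError("cursor needs a valid length-k window")
        self.k = k
        self.codes = list(int(c) for c in codes)
        hf = 0
        for c in self.codes:
            hf = (hf * H.BASE + c) & H.M64
        hr = 0
        for c in reversed(self.codes):
            hr = (hr * H.BASE + (5 - c)) & H.M64
        self.hf = hf
        self.hr = hr
        self._powk1 = H.pow_base(k - 1)

    def canonical(self) -> int:
        return min(self.hf, self.hr)

    def neighbor_hashes(self) -> tuple[list[int], list[int]]:
        """(forward, rc) hashes of the four suffix extensions."""
        x0 = self.codes[0]
        stem_f = ((self.hf - x0 * self._powk1) * H.BASE) & H.M64
        stem_r = ((self.hr - (5 - x0)) * H.BASE_INV) & H.M64
        fwd = [(stem_f + b) & H.M64 for b in (1, 2, 3, 4)]
        rev = [(stem_r + (5 - b) * self._powk1) & H.M64 for b in (1, 2, 3, 4)]
        return fwd, rev

    def advance(self, b: int) -> None:
        x0 = self.codes.pop(0)
        self.codes.append(b)
        self.hf = (((self.hf - x0 * self._powk1) * H.BASE) + b) & H.M64
        self.hr = ((self.hr - (5 - x0)) * H.BASE_INV + (5 - b) * self._powk1) & H.M64


def _suffix_neighbor_counts(index: KmerIndex, cur: _Cursor, k: int):
    """Per-base (count_rc, strand_validated) for the four suffix neighbors."""
    fwd, rev = cur.neighbor_hashes()
    table = index._table(k)
    counts = table.lookup_many(np.array(fwd + rev, dtype=np.uint64))
    cf, cr = counts[:4], counts[4:]
    validated = (cf > 0) & (cr > 0)
    return cf + cr, validated


@dataclass
class FragmentSizeDistribution:
    lengths: list[int] = field(default_factory=list)
    n_attempted: int = 0
    n_resolved: int = 0

    def mean(self) -> float:
        return float(np.mean(self.lengths)) if self.lengths else float("nan")

    def sd(self) -> float:
        return float(np.std(self.lengths, ddof=1)) if len(self.lengths) > 1 else float("nan")


def estimate_fragment_sizes(
    index: KmerIndex,
    n_pairs: int = 100_000,
    k: int = FRAGMENT_WALK_K,
    max_steps: int = FRAGMENT_MAX_STEPS,
    rng=None,
    orientation: str = "fr",
) -> FragmentSizeDistribution:
    """Fragment sizes from greedy walks between sampled read-pair ends.

    ``orientation`` is the expected mate layout: "fr" (forward/reverse, the
    default) walks toward the first k-mer of the reverse complement of the
    mate; "ff" (forward/forward) walks toward the mate's first k-mer as is.
    """
    if orientation not in ("fr", "ff"):
        raise ValueError("orientation must be 'fr' or 'ff'")
    if not index.reads.paired:
        raise ValueError("fragment-size estimation requires a paired ReadSet")
    rng = np.random.default_rng(rng)
    n_avail = index.n_reads // 2
    if n_pairs >= n_avail:
        pairs = np.arange(n_avail)
    else:
        pairs = rng.choice(n_avail, size=n_pairs, replace=False)
    out = FragmentSizeDistribution()
    for p in pairs:
        x = index.reads[2 * int(p)]
        y = index.reads[2 * int(p) + 1]
        out.n_attempted += 1
        if len(x.seq) < k or len(y.seq) < k:
            continue
        start_codes = H.encode(x.seq[:k])
        try:
            mate = reverse_complement(y.seq) if orientation == "fr" else y.seq
            target = H.hash_str(mate[:k])
        except ValueError:
            target = None
        if target is None or (start_codes == 0).any():
            continue
        try:
            cur = _Cursor(start_codes, k)
        except ValueError:
            continue
        steps = 0
        found = cur.hf == target
        while not found and steps < max_steps:
            crc, validated = _suffix_neighbor_counts(index, cur, k)
            crc = np.where(validated, crc, -1)
            if crc.max() <= 0:
                break  # dead end
            cur.advance(int(np.argmax(crc)) + 1)
            steps += 1
            found = cur.hf == target
        if found:
            out.lengths.append(steps + len(y.seq))
            out.n_resolved += 1
    return out


@dataclass
class WalkSummaryEntry:
    k: int
    lengths: list[int]
    n50: int
    n_walks: int
    lam: float


@dataclass
class WalkSummary:
    entries: list[WalkSummaryEntry] = field(default_factory=list)
    skipped: list[tuple[int, str]] = field(default_factory=list)


def _assembly_direction(
    index: KmerIndex,
    cur: _Cursor,
    k: int,
    params: ClassifierParams,
    visited: set[int],
    max_len: int,
) -> int:
    """Extend greedily from ``cur``; returns number of new k-mers visited."""
    table_k1 = index._table(k + 1)
    powk = H.pow_base(k)
    n_new = 0
    while len(visited) < max_len:
        crc, validated = _suffix_neighbor_counts(index, cur, k)
        masked = np.where(validated, crc, -1)
        n_valid = int(validated.sum())
        if n_valid == 0:
            break
        if n_valid >= 2:
            order = np.argsort(-masked, kind="stable")
            a, b = int(order[0]), int(order[1])
            c_a, c_b = int(masked[a]), int(masked[b])
            c_ia = table_k1.lookup((cur.hf * H.BASE + a + 1) & H.M64) + table_k1.lookup(
                ((5 - (a + 1)) * powk + cur.hr) & H.M64
            )
            c_ib = table_k1.lookup((cur.hf * H.BASE + b + 1) & H.M64) + table_k1.lookup(
                ((5 - (b + 1)) * powk + cur.hr) & H.M64
            )
            d = max(0, (c_a - c_ia) + (c_b - c_ib))
            post = _classify_arrays(
                np.array([c_a]), np.array([c_b]), np.array([d]), params
            )[0]
            if int(np.argmax(post)) == 2:  # repeat branch terminates the walk
                break
        cur.advance(int(np.argmax(masked)) + 1)
        can = cur.canonical()
        if can in visited:
            break
        visited.add(can)
        n_new += 1
    return n_new


def simulate_assembly(
    reads,
    k_values=tuple(range(21, 92, 5)),
    n_walks: int = 20_000,
    max_len: int = ASSEMBLY_MAX_LEN,
    rng=None,
    hist_reads: int = 50_000,
    hom_start_threshold: float = 0.50,
    bloom_capacity: int | None = None,
) -> WalkSummary:
    """Walks mimicking an assembler that resolves error and variant branches.

    Per k: the count mixture is refit, then up to ``n_walks`` sampled reads
    seed bidirectional greedy walks. Reads whose first k-mer has homozygous
    posterior below 0.5, contains N, or already sits in the Bloom filter are
    skipped (consuming an attempt), so fewer walks may be returned.
    """
    rng = np.random.default_rng(rng)
    out = WalkSummary()
    for k in k_values:
        try:
            index = KmerIndex(reads, [k, k + 1])
        except ValueError as exc:
            out.skipped.append((k, str(exc)))
            continue
        hist = sample_count_histogram(index, k, hist_reads, rng)
        model = fit_mixture_em(hist)
        params = ClassifierParams.from_model(model, index.modal_read_length, k)
        hom_table = model.posterior_homozygous_table()
        cap = hom_table.size - 1
        capacity = bloom_capacity or min(
            index.reads.n_bases, n_walks * max_len // 10 + 1024
        )
        bloom = BloomFilter(capacity)
        lengths: list[int] = []
        for _ in range(n_walks):
            rid = int(rng.integers(0, index.n_reads))
            seq = index.reads[rid].seq
            if len(seq) < k:
                continue
            codes = H.encode(seq[:k])
            if (codes == 0).any():
                continue
            cur = _Cursor(codes, k)
            crc = index._table(k).lookup(cur.hf) + index._table(k).lookup(cur.hr)
            if crc < 1 or hom_table[min(crc, cap)] < hom_start_threshold:
                continue
            if cur.canonical() in bloom:
                continue
            visited = {cur.canonical()}
            fwd = _assembly_direction(index, cur, k, params, visited, max_len)
            rcur = _Cursor(H.rc_codes(codes)[::-1], k)
            rev = _assembly_direction(index, rcur, k, params, visited, max_len)
            for h in visited:
                bloom.add(h)
            lengths.append(1 + fwd + rev)
        out.entries.append(
            WalkSummaryEntry(k, lengths, n50(lengths), len(lengths), model.lam)
        )
    return out
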