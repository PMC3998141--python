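"""Read-level quality metrics: overlap-consensus per-base error rates,
quality-by-position summaries and coverage/GC diagnostics.

The error-rate estimator samples reads, finds overlap candidates seeded by
shared 31-mers (skipping seeds seen more than 200 times, to avoid repeat
pile-ups), computes ungapped overlaps at the seed diagonal (>= 50 bp, >= 95%
identity), stacks them into a multiple alignment in the sampled read's frame
and calls a base an error when it disagrees with a consensus supported by at
least three reads while fewer than four reads support the base itself.
Columns covered by fewer than four reads are not assessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _hashing as H
from .count_model import CountHistogram, sample_count_histogram
from .seqio import Read, ReadSet

logger = logging.getLogger(__name__)

DEFAULT_SEED_LEN = 31
DEFAULT_MAX_SEED_COUNT = 200
MIN_OVERLAP = 50
MIN_IDENTITY = 0.95
MIN_CONSENSUS_SUPPORT = 3
MAX_ERROR_SUPPORT = 4  # a base supported by >= 4 reads is never called an error
MIN_ASSESSED_DEPTH = 4


class OverlapSeedIndex:
    """Inverted index: seed k-mer hash -> (read, position) occurrences."""

    def __init__(self, reads: ReadSet, seed_len: int = DEFAULT_SEED_LEN):
        self.reads = reads
        self.seed_len = seed_len
        hashes, rids, poss = [], [], []
        for rid, r in enumerate(reads):
            codes = H.encode(r.seq)
            hf = H.window_hashes(codes, seed_len)
            valid = H.window_valid(codes, seed_len)
            idx = np.flatnonzero(valid)
            hashes.append(hf[idx])
            rids.append(np.full(idx.size, rid, dtype=np.int32))
            poss.append(idx.astype(np.int32))
        h = np.concatenate(hashes) if hashes else np.empty(0, np.uint64)
        order = np.argsort(h, kind="stable")
        self._hashes = h[order]
        self._rids = np.concatenate(rids)[order] if rids else np.empty(0, np.int32)
        self._poss = np.concatenate(poss)[order] if poss else np.empty(0, np.int32)

    def _range(self, h: int) -> tuple[int, int]:
        lo = int(np.searchsorted(self._hashes, np.uint64(h), side="left"))
        hi = int(np.searchsorted(self._hashes, np.uint64(h), side="right"))
        return lo, hi

    def occurrences(self, h: int):
        lo, hi = self._range(h)
        return self._rids[lo:hi], self._poss[lo:hi]

    def seed_count_rc(self, hf: int, hr: int) -> int:
        lo, hi = self._range(hf)
        lo2, hi2 = self._range(hr)
        return (hi - lo) + (hi2 - lo2)


@dataclass
class SeedPlacement:
    """First shared seed between R and a candidate read."""

    read_id: int
    pos_r: int
    pos_s: int
    reverse: bool
    seed_len: int = DEFAULT_SEED_LEN


def _seed_placements(
    seed_index: OverlapSeedIndex,
    read: Read,
    self_id: int | None,
    max_seed_count: int,
) -> dict[int, SeedPlacement]:
    """First seed placement per candidate read, scanning R left to right.

    Seeds occurring more than ``max_seed_count`` times in the reads (both
    strands combined) contribute no candidates.
    """
    k = seed_index.seed_len
    codes = H.encode(read.seq)
    hf, hr, valid = H.paired_window_hashes(codes, k)
    placements: dict[int, SeedPlacement] = {}
    for i in np.flatnonzero(valid):
        f, r = int(hf[i]), int(hr[i])
        if seed_index.seed_count_rc(f, r) > max_seed_count:
            continue
        rids, poss = seed_index.occurrences(f)
        for rid, pos in zip(rids, poss):
            rid = int(rid)
            if rid == self_id or rid in placements:
                continue
            placements[rid] = SeedPlacement(rid, int(i), int(pos), False, k)
        rids, poss = seed_index.occurrences(r)
        for rid, pos in zip(rids, poss):
            rid = int(rid)
            if rid == self_id or rid in placements:
                continue
            placements[rid] = SeedPlacement(rid, int(i), int(pos), True, k)
    return placements


def overlap_candidates(
    seed_index: OverlapSeedIndex,
    read: Read,
    self_id: int | None = None,
    max_seed_count: int = DEFAULT_MAX_SEED_COUNT,
) -> set[int]:
    """Indices of reads sharing a usable seed with ``read`` (either strand)."""
    return set(_seed_placements(seed_index, read, self_id, max_seed_count))


@dataclass
class Overlap:
    r_start: int
    r_end: int
    s_codes: np.ndarray  # candidate bases (codes 0..4) in R's frame
    n_mismatch: int
    identity: float
    reverse: bool


def compute_overlap(
    r_read: Read,
    s_read: Read,
    placement: SeedPlacement,
    min_overlap: int = MIN_OVERLAP,
    min_identity: float = MIN_IDENTITY,
) -> Overlap | None:
    """Ungapped overlap at the diagonal fixed by the seed, in R's frame.

    Returns None when the overlapping interval is shorter than
    ``min_overlap`` or identity falls below ``min_identity``.
    """
    r_codes = H.encode(r_read.seq)
    s_codes = H.encode(s_read.seq)
    pos_s = placement.pos_s
    if placement.reverse:
        s_codes = H.rc_codes(s_codes)[::-1]
        pos_s = len(s_read.seq) - placement.pos_s - placement.seed_len
    diag = pos_s - placement.pos_r
    r0 = max(0, -diag)
    r1 = min(len(r_read.seq), len(s_read.seq) - diag)
    if r1 - r0 < min_overlap:
        return None
    seg_r = r_codes[r0:r1]
    seg_s = s_codes[r0 + diag : r1 + diag]
    both = (seg_r > 0) & (seg_s > 0)
    mism = int(np.count_nonzero((seg_r != seg_s) & both))
    length = r1 - r0
    identity = 1.0 - mism / length
    if identity < min_identity:
        return None
    return Overlap(r0, r1, seg_s, mism, identity, placement.reverse)


@dataclass
class ErrorProfile:
    """Per-position error counts over assessed bases; rate(j) = err/tot."""

    err: np.ndarray
    tot: np.ndarray
    n_sampled_reads: int = 0

    def rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.tot > 0, self.err / np.maximum(self.tot, 1), np.nan)


def per_base_error_rate(
    reads: ReadSet,
    n_sample_reads: int = 100_000,
    rng=None,
    seed_len: int = DEFAULT_SEED_LEN,
    max_seed_count: int = DEFAULT_MAX_SEED_COUNT,
    min_overlap: int = MIN_OVERLAP,
    min_identity: float = MIN_IDENTITY,
    seed_index: OverlapSeedIndex | None = None,
) -> ErrorProfile:
    """Overlap/consensus per-base error-rate profile over sampled reads."""
    rng = np.random.default_rng(rng)
    if seed_index is None:
        seed_index = OverlapSeedIndex(reads, seed_len)
    n = len(reads)
    if n_sample_reads >= n:
        sel = np.arange(n)
    else:
        sel = rng.choice(n, size=n_sample_reads, replace=False)
    max_len = reads.max_read_length
    err = np.zeros(max_len, dtype=np.int64)
    tot = np.zeros(max_len, dtype=np.int64)

    for rid in sel:
        r_read = reads[int(rid)]
        l = len(r_read.seq)
        placements = _seed_placements(
            seed_index, r_read, int(rid), max_seed_count
        )
        r_codes = H.encode(r_read.seq)
        # pileup over codes 1..4 (row 0 collects Ns, excluded from support)
        counts = np.zeros((5, l), dtype=np.int32)
        counts[r_codes, np.arange(l)] += 1
        for placement in placements.values():
            ov = compute_overlap(
                r_read,
                reads[placement.read_id],
                placement,
                min_overlap,
                min_identity,
            )
            if ov is None:
                continue
            cols = np.arange(ov.r_start, ov.r_end)
            counts[ov.s_codes, cols] += 1
        support = counts[1:]  # A,C,G,T support per column
        depth = support.sum(axis=0)
        col_max = support.max(axis=0)
        cons = support.argmax(axis=0) + 1
        own = np.where(r_codes > 0, support[np.maximum(r_codes - 1, 0), np.arange(l)], 0)
        # ties (and the common case) resolve toward R's own base
        cons = np.where((r_codes > 0) & (own == col_max), r_codes, cons)
        cons_support = support[cons - 1, np.arange(l)]
        assessed = (depth >= MIN_ASSESSED_DEPTH) & (r_codes > 0)
        is_err = (
            assessed
            & (r_codes != cons)
            & (cons_support >= MIN_CONSENSUS_SUPPORT)
            & (own < MAX_ERROR_SUPPORT)
        )
        tot[:l] += assessed
        err[:l] += is_err
    return ErrorProfile(err, tot, n_sampled_reads=len(sel))


@dataclass
class QualityProfile:
    """Per-position mean and decile summary of Phred scores."""

    mean: np.ndarray
    deciles: np.ndarray  # shape (9, read_len): 10th..90th percentiles
    n_sampled_reads: int = 0


def quality_by_position(
    reads: ReadSet, n_samples: int = 100_000, rng=None
) -> QualityProfile:
    rng = np.random.default_rng(rng)
    n = len(reads)
    sel = (
        np.arange(n)
        if n_samples >= n
        else rng.choice(n, size=n_samples, replace=False)
    )
    max_len = reads.max_read_length
    cols: list[list[int]] = [[] for _ in range(max_len)]
    for rid in sel:
        q = np.frombuffer(reads[int(rid)].qual.encode(), dtype=np.uint8) - 33
        for j, v in enumerate(q):
            cols[j].append(int(v))
    mean = np.array([np.mean(c) if c else np.nan for c in cols])
    dec = np.full((9, max_len), np.nan)
    for j, c in enumerate(cols):
        if c:
            dec[:, j] = np.percentile(c, np.arange(10, 100, 10))
    return QualityProfile(mean, dec, n_sampled_reads=len(sel))


def kmer_count_histogram_51(
    index, n_samples: int = 50_000, rng=None, k: int = 51
) -> CountHistogram:
    """Fixed-k count histogram for the report (default k = 51)."""
    return sample_count_histogram(index, k, n_samples, rng)


@dataclass
class GCCoverageHistogram:
    """2-D histogram of (GC fraction, k-mer count) over sampled k-mers."""

    k: int
    gc_edges: np.ndarray
    count_edges: np.ndarray
    matrix: np.ndarray  # rows: GC bins, cols: count bins

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def gc_coverage_histogram(
    index,
    k: int = 51,
    n_samples: int = 50_000,
    gc_bins: int = 20,
    max_count: int = 200,
    rng=None,
) -> GCCoverageHistogram:
    """GC fraction of each sampled k-mer against its count_rc.

    GC is computed on the k-mer itself; GC bins are left-closed over [0, 1]
    (the final bin closed); counts above ``max_count`` collapse into the
    last column.
    """
    rng = np.random.default_rng(rng)
    sel = index.sample_read_indices(n_samples, rng)
    codes = index.selected_codes(sel)
    crc, _, _, valid, _ = index.window_count_rc(codes, k)
    gc_flag = ((codes == 2) | (codes == 3)).astype(np.int64)
    cg = np.concatenate(([0], np.cumsum(gc_flag)))
    gc_frac = (cg[k:] - cg[:-k]) / k
    gc_frac = gc_frac[valid]
    crc = np.minimum(crc[valid], max_count)

    gc_edges = np.linspace(0.0, 1.0, gc_bins + 1)
    gc_bin = np.minimum((gc_frac * gc_bins).astype(int), gc_bins - 1)
    count_edges = np.arange(1, max_count + 2)
    cnt_bin = np.clip(crc, 1, max_count) - 1
    matrix = np.zeros((gc_bins, max_count), dtype=np.int64)
    np.add.at(matrix, (gc_bin, cnt_bin), 1)
    return GCCoverageHistogram(k, gc_edges, count_edges, matrix)
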