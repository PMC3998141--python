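"""Overlap-consensus error rates, quality and GC/coverage diagnostics."""

import numpy as np
import pytest

from conftest import make_readset
from preqc import KmerIndex
from preqc.read_metrics import (
    OverlapSeedIndex,
    SeedPlacement,
    compute_overlap,
    gc_coverage_histogram,
    overlap_candidates,
    per_base_error_rate,
    quality_by_position,
)
from preqc.seqio import Read, ReadSet, reverse_complement
from preqc.simulate import simulate_diploid_genome, simulate_reads


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# -- candidates ------------------------------------------------------------


def test_overlap_candidates_exact_set(rng):
    base = _random_seq(rng, 200)
    r = base[50:150]
    others = [base[40:140], base[60:160], base[45:145],
              reverse_complement(base[55:155]), base[70:170]]
    decoys = [_random_seq(rng, 100) for _ in range(5)]
    reads = make_readset([r] + others + decoys)
    sidx = OverlapSeedIndex(reads)
    assert overlap_candidates(sidx, reads[0], self_id=0) == {1, 2, 3, 4, 5}


def test_overlap_candidates_no_shared_seed(rng):
    reads = make_readset([_random_seq(rng, 100) for _ in range(4)])
    sidx = OverlapSeedIndex(reads)
    assert overlap_candidates(sidx, reads[0], self_id=0) == set()


def test_seed_count_cap_boundary(rng):
    """A seed seen exactly 200 times still yields candidates; 201 does not."""
    seq = _random_seq(rng, 31)
    for n_copies, expect in [(200, True), (201, False)]:
        reads = make_readset([seq] * n_copies)
        sidx = OverlapSeedIndex(reads)
        got = overlap_candidates(sidx, reads[0], self_id=0)
        assert bool(got) is expect


# -- pairwise overlaps -----------------------------------------------------


def test_identical_reads_full_overlap(rng):
    s = _random_seq(rng, 100)
    ra, rb = Read("a", s, "I" * 100), Read("b", s, "I" * 100)
    ov = compute_overlap(ra, rb, SeedPlacement(1, 0, 0, False))
    assert ov is not None
    assert (ov.r_start, ov.r_end) == (0, 100)
    assert ov.identity == 1.0 and ov.n_mismatch == 0


def test_overlap_with_mismatches_accepted(rng):
    base = _random_seq(rng, 160)
    r = base[:100]
    s = list(base[40:140])
    s[10] = "A" if s[10] != "A" else "C"
    s[30] = "A" if s[30] != "A" else "C"
    rb = Read("b", "".join(s), "I" * 100)
    ra = Read("a", r, "I" * 100)
    # shared seed somewhere in the clean tail of the 60 bp overlap
    ov = compute_overlap(ra, rb, SeedPlacement(1, 75, 35, False))
    assert ov is not None
    assert ov.r_end - ov.r_start == 60
    assert ov.n_mismatch == 2
    assert ov.identity == pytest.approx(1 - 2 / 60)


def test_overlap_length_threshold(rng):
    base = _random_seq(rng, 160)
    ra = Read("a", base[:100], "I" * 100)
    rb = Read("b", base[60:160], "I" * 100)  # 40 bp overlap only
    assert compute_overlap(ra, rb, SeedPlacement(1, 65, 5, False)) is None


def test_overlap_identity_threshold_boundary(rng):
    """60 bp with 3 mismatches is exactly 95% (kept); 4 is rejected."""
    base = _random_seq(rng, 160)
    ra = Read("a", base[:100], "I" * 100)
    for n_mm, kept in [(3, True), (4, False)]:
        s = list(base[40:140])
        for j in range(n_mm):
            s[5 + j] = "A" if s[5 + j] != "A" else "C"
        rb = Read("b", "".join(s), "I" * 100)
        ov = compute_overlap(ra, rb, SeedPlacement(1, 75, 35, False))
        assert (ov is not None) is kept


def test_overlap_reverse_strand(rng):
    base = _random_seq(rng, 150)
    ra = Read("a", base[:100], "I" * 100)
    rb = Read("b", reverse_complement(base[20:120]), "I" * 100)
    # rb contains rc of ra's seed at position 100 - (30 - 20) - 31 = 59
    ov = compute_overlap(ra, rb, SeedPlacement(1, 30, 59, True))
    assert ov is not None
    assert (ov.r_start, ov.r_end) == (20, 100)
    assert ov.identity == 1.0


# -- consensus error calling ----------------------------------------------


def _identical_cohort(rng, n=11, length=100):
    s = _random_seq(rng, length)
    return s, [list(s) for _ in range(n)]


def test_single_mismatch_hand_fixture(rng):
    s, seqs = _identical_cohort(rng)
    seqs[4][3] = "A" if s[3] != "A" else "C"  # one read errs at position 3
    reads = make_readset(["".join(x) for x in seqs])
    prof = per_base_error_rate(reads, n_sample_reads=len(reads), rng=0)
    rate = prof.rate()
    assert rate[3] == pytest.approx(1 / 11)
    assert np.all(rate[np.arange(100) != 3] == 0)
    assert np.all(prof.tot == 11)


def test_error_free_reads_have_zero_rate(small_reads):
    sub = ReadSet(list(small_reads)[:400])
    prof = per_base_error_rate(sub, n_sample_reads=100, rng=1)
    assert prof.err.sum() == 0
    assert prof.tot.sum() > 0


def test_consensus_support_threshold_boundary(rng):
    """Consensus supported by 3 reads flags a disagreeing base; by 2 not."""
    s, seqs = _identical_cohort(rng, n=4)
    seqs[0][10] = "A" if s[10] != "A" else "C"  # one read disagrees with x3
    reads = make_readset(["".join(x) for x in seqs])
    prof = per_base_error_rate(reads, n_sample_reads=len(reads), rng=0)
    assert prof.err[10] == 1
    # consensus support drops to 2: another read mutated to a third base
    third = ({"A", "C", "G", "T"} - {s[10], seqs[0][10]}).pop()
    seqs[1][10] = third
    reads2 = make_readset(["".join(x) for x in seqs])
    prof2 = per_base_error_rate(reads2, n_sample_reads=len(reads2), rng=0)
    assert prof2.err[10] == 0


def test_own_support_threshold_boundary(rng):
    """A base supported by 4 reads is never an error; by 3 it can be."""
    s, seqs = _identical_cohort(rng, n=9)
    alt = "A" if s[20] != "A" else "C"
    for i in range(4):  # four reads carry the alternative base
        seqs[i][20] = alt
    reads = make_readset(["".join(x) for x in seqs])
    prof = per_base_error_rate(reads, n_sample_reads=len(reads), rng=0)
    assert prof.err[20] == 0
    seqs[3][20] = s[20]  # now only 3 reads support the alternative
    reads2 = make_readset(["".join(x) for x in seqs])
    prof2 = per_base_error_rate(reads2, n_sample_reads=len(reads2), rng=0)
    assert prof2.err[20] == 3  # each alternative-carrying read is flagged


def test_low_depth_columns_not_assessed(rng):
    s, seqs = _identical_cohort(rng, n=3)
    reads = make_readset(["".join(x) for x in seqs])
    prof = per_base_error_rate(reads, n_sample_reads=len(reads), rng=0)
    assert prof.tot.sum() == 0  # depth 3 < 4 everywhere


# -- quality ---------------------------------------------------------------


def test_quality_constant_q30():
    reads = make_readset(["ACGT" * 10] * 5, qual_char="?")
    q = quality_by_position(reads, 100, rng=0)
    assert np.allclose(q.mean, 30.0)


def test_quality_two_levels():
    q20, q40 = chr(33 + 20), chr(33 + 40)
    reads = ReadSet([
        Read("a", "ACGT", q20 * 4),
        Read("b", "ACGT", q40 * 4),
    ])
    q = quality_by_position(reads, 10, rng=0)
    assert np.allclose(q.mean, 30.0)
    assert q.deciles[0, 0] >= 20 and q.deciles[-1, 0] <= 40


# -- GC / coverage ---------------------------------------------------------


def test_gc_histogram_extremes_and_mass():
    reads = make_readset(["ATAT" * 5, "GCGC" * 5, "AACCGGTT" * 3])
    idx = KmerIndex(reads, [8])
    g = gc_coverage_histogram(idx, k=8, n_samples=10, gc_bins=4, rng=0)
    n_windows = sum(len(r.seq) - 8 + 1 for r in reads)
    assert g.total == n_windows
    assert g.matrix[0].sum() > 0   # GC = 0 bin populated by ATAT
    assert g.matrix[-1].sum() > 0  # GC = 1 bin populated by GCGC
    assert g.matrix[1:3].sum() > 0


def test_gc_uniform_coverage_within_sampling_error():
    genome = simulate_diploid_genome(60_000, 0.0, seed=51)
    reads = simulate_reads(genome, 30, seed=52)
    idx = KmerIndex(reads, [31])
    g = gc_coverage_histogram(idx, k=31, n_samples=3000, gc_bins=10, rng=53)
    mids = (g.count_edges[:-1] + 0.0)
    means, weights = [], []
    for row in g.matrix:
        tot = row.sum()
        if tot >= 2000:  # well-populated GC columns only
            means.append(float((row * mids).sum() / tot))
            weights.append(tot)
    assert len(means) >= 3
    grand = np.average(means, weights=weights)
    for m, w in zip(means, weights):
        sigma = grand / np.sqrt(w)  # Poisson-scale spread of the column mean
        assert abs(m - grand) < 4 * sigma + 0.5
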