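"""Shared fixtures: small deterministic genomes and read sets.

Heavier simulated datasets are session-scoped so the cost is paid once.
"""

import numpy as np
import pytest

from preqc import (
    KmerIndex,
    simulate_diploid_genome,
    simulate_reads,
)
from preqc.seqio import Read, ReadSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_readset(seqs, paired=False, qual_char="?"):
    return ReadSet(
        [Read(f"r{i}", s, qual_char * len(s)) for i, s in enumerate(seqs)],
        paired=paired,
    )


@pytest.fixture
def tiny_reads():
    return make_readset(["ACGTA", "TACGT"])


@pytest.fixture(scope="session")
def small_genome():
    """20 kb haploid-style genome (het 0) used across index/count tests."""
    return simulate_diploid_genome(20_000, 0.0, seed=101)


@pytest.fixture(scope="session")
def small_reads(small_genome):
    """Error-free paired 30X reads over the 20 kb genome."""
    return simulate_reads(small_genome, 30, seed=102)


@pytest.fixture(scope="session")
def small_index(small_reads):
    return KmerIndex(small_reads, [21, 22, 31, 51])


@pytest.fixture(scope="session")
def diploid_genome():
    """50 kb diploid genome with heterozygosity and diverged repeats."""
    return simulate_diploid_genome(
        50_000,
        1e-3,
        repeat_spec=[(500, 6, 1)],
        seed=103,
        repeat_divergence=0.05,
    )


@pytest.fixture(scope="session")
def diploid_reads(diploid_genome):
    return simulate_reads(
        diploid_genome,
        40,
        error_rate_by_pos=np.full(100, 0.005),
        seed=104,
    )
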