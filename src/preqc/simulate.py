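"""Synthetic diploid genomes and error-bearing paired reads.

The generator emulates the assumptions of the downstream models: a diploid
genome whose haplotypes differ by isolated heterozygous substitutions, with
planted interspersed repeat families, sequenced as uniformly placed fragments
with position-specific substitution errors. Indels — in the genome or in the
reads — are deliberately absent: the count and branch models are
substitution-oriented.

Repeat copies may optionally be diverged from their family consensus
(``repeat_divergence`` substitutions per base, default 0 = identical copies).
Diverged copies are what give rise to repeat branches at single-copy vertices
of the k-mer graph — two loci sharing a (k-1)-mer context that then diverges —
which is the structure the branch classifier detects on real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Read, ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_QUAL_CHAR = "?"  # Phred+33 for Q30


@dataclass
class DiploidGenome:
    """Two haplotypes plus the ground truth that separates them.

    ``truth`` lists heterozygous sites as (position, hap_a base, hap_b base);
    ``repeat_annotation`` lists planted repeat copies as
    (start, unit_length, copy_count of the owning family).
    """

    hap_a: str
    hap_b: str
    truth: list[tuple[int, str, str]] = field(default_factory=list)
    repeat_annotation: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.hap_a) != len(self.hap_b):
            raise ValueError("haplotypes must have equal length")
        positions = [p for p, _, _ in self.truth]
        if len(positions) != len(set(positions)):
            raise ValueError("heterozygous positions must be distinct")

    def __len__(self) -> int:
        return len(self.hap_a)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _place_repeats(
    genome: np.ndarray,
    repeat_spec,
    rng: np.random.Generator,
    divergence: float,
) -> list[tuple[int, int, int]]:
    length = genome.size
    total = sum(u * c * f for u, c, f in repeat_spec)
    if total > length:
        raise ValueError(
            f"repeat specification covers {total} bp, exceeding the "
            f"{length} bp genome"
        )
    occupied: list[tuple[int, int]] = []
    annotation = []
    for unit_len, copy_count, family_count in repeat_spec:
        if unit_len <= 0 or copy_count <= 0 or family_count <= 0:
            raise ValueError("repeat_spec entries must be positive")
        for _ in range(family_count):
            unit = rng.integers(0, 4, unit_len)
            for _ in range(copy_count):
                for _attempt in range(1000):
                    s = int(rng.integers(0, length - unit_len + 1))
                    if all(s + unit_len <= a or s >= b for a, b in occupied):
                        break
                else:
                    raise ValueError(
                        "could not place repeat copies without overlap; "
                        "repeat specification too dense for genome length"
                    )
                copy = unit.copy()
                if divergence > 0:
                    mut = np.flatnonzero(rng.random(unit_len) < divergence)
                    copy[mut] = (copy[mut] + rng.integers(1, 4, mut.size)) % 4
                genome[s : s + unit_len] = copy
                occupied.append((s, s + unit_len))
                annotation.append((s, unit_len, copy_count))
    annotation.sort()
    return annotation


def simulate_diploid_genome(
    length_bp: int,
    het_rate: float,
    repeat_spec=(),
    seed: int = 0,
    repeat_divergence: float = 0.0,
) -> DiploidGenome:
    """Simulate a diploid genome with planted repeats and heterozygous SNVs.

    Parameters
    ----------
    length_bp : haploid genome length.
    het_rate : per-base probability of a heterozygous substitution (< 0.1).
    repeat_spec : iterable of (unit_length, copy_count, family_count); each
        family is one random unit planted copy_count times at random
        non-overlapping positions.
    repeat_divergence : per-base substitution rate of each planted copy away
        from its family consensus (0 = identical copies).
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if not 0 <= het_rate < 0.1:
        raise ValueError("het_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    hap_a = rng.integers(0, 4, length_bp).astype(np.int64)
    annotation = _place_repeats(hap_a, repeat_spec, rng, repeat_divergence)

    hap_b = hap_a.copy()
    truth: list[tuple[int, str, str]] = []
    if het_rate > 0:
        sites = np.flatnonzero(rng.random(length_bp) < het_rate)
        alt = (hap_a[sites] + rng.integers(1, 4, sites.size)) % 4
        hap_b[sites] = alt
        truth = [
            (int(p), chr(_BASES[hap_a[p]]), chr(_BASES[hap_b[p]]))
            for p in sites
        ]
    return DiploidGenome(
        _codes_to_str(hap_a), _codes_to_str(hap_b), truth, annotation
    )


def simulate_reads(
    genome: DiploidGenome,
    coverage: float,
    read_len: int = 100,
    error_rate_by_pos=None,
    fragment_mean: float = 300.0,
    fragment_sd: float = 30.0,
    paired: bool = True,
    seed: int = 0,
    batch_size: int = 100_000,
) -> ReadSet:
    """Simulate (paired) reads from a random haplotype at the given coverage.

    Fragments are placed uniformly on a haplotype chosen at random per
    fragment; fragment lengths are Normal(fragment_mean, fragment_sd) clipped
    to [read_len, genome length]. Mates are emitted in forward/reverse-
    complement orientation, interleaved. Per-base substitution errors are
    applied independently with the position-specific probabilities
    ``error_rate_by_pos`` (default: error-free). Qualities are constant Q30.

    Coverage is total sequenced bases divided by the haploid genome length.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(genome)
    if read_len > L:
        raise ValueError("read_len exceeds genome length")
    if paired and fragment_mean < read_len:
        raise ValueError("fragment_mean must be >= read_len for paired reads")
    if error_rate_by_pos is None:
        error_rate_by_pos = np.zeros(read_len)
    error_rate_by_pos = np.asarray(error_rate_by_pos, dtype=float)
    if error_rate_by_pos.shape != (read_len,):
        raise ValueError("error_rate_by_pos must have length read_len")

    rng = np.random.default_rng(seed)
    haps = np.stack(
        [
            np.frombuffer(genome.hap_a.encode(), dtype=np.uint8),
            np.frombuffer(genome.hap_b.encode(), dtype=np.uint8),
        ]
    )
    # map ASCII -> 0..3 for error arithmetic
    lut = np.zeros(256, dtype=np.uint8)
    lut[_BASES] = np.arange(4)
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)  # code complement

    bases_per_unit = 2 * read_len if paired else read_len
    n_units = max(1, int(round(coverage * L / bases_per_unit)))

    reads: list[Read] = []
    qual = _DEFAULT_QUAL_CHAR * read_len
    offsets = np.arange(read_len)

    def _apply_errors(mat: np.ndarray) -> np.ndarray:
        err = rng.random(mat.shape) < error_rate_by_pos[None, :]
        if err.any():
            shift = rng.integers(1, 4, mat.shape)
            mat = np.where(err, (mat + shift) % 4, mat)
        return mat

    serial = 0
    for lo in range(0, n_units, batch_size):
        n = min(batch_size, n_units - lo)
        hap_idx = rng.integers(0, 2, n)
        if paired:
            frag = np.rint(rng.normal(fragment_mean, fragment_sd, n))
            frag = np.clip(frag, read_len, L).astype(np.int64)
        else:
            frag = np.full(n, read_len, dtype=np.int64)
        start = (rng.random(n) * (L - frag + 1)).astype(np.int64)
        hap_col = hap_idx[:, None]
        r1 = lut[haps[hap_col, start[:, None] + offsets]]
        r1 = _apply_errors(r1.astype(np.uint8))
        if paired:
            m_start = start + frag - read_len
            r2 = lut[haps[hap_col, m_start[:, None] + offsets]]
            r2 = comp[r2[:, ::-1]]  # reverse-complement orientation
            r2 = _apply_errors(r2)
        for i in range(n):
            name = f"sim:{serial}"
            reads.append(Read(name + "/1", _codes_to_str(r1[i]), qual))
            if paired:
                reads.append(Read(name + "/2", _codes_to_str(r2[i]), qual))
            serial += 1
    return ReadSet(reads, paired=paired)
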