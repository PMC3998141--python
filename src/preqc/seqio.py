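"""Reads, read sets and FASTQ I/O.

FASTQ records (4-line, Phred+33) are parsed with Biopython's fast iterator;
gzip compression is handled transparently by file magic. Paired data follows
the interleaved convention: reads 2i and 2i+1 are mates.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

_ALLOWED = set("ACGTNacgtn")
_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(p: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case-preserving)."""
    if not set(p) <= _ALLOWED:
        bad = sorted(set(p) - _ALLOWED)
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return p.translate(_RC_TABLE)[::-1]


@dataclass
class Read:
    """A single sequencing read: identifier, sequence and Phred+33 qualities."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: sequence/quality length mismatch "
                f"({len(self.seq)} vs {len(self.qual)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadSet:
    """Ordered collection of reads; when paired, reads 2i and 2i+1 are mates."""

    reads: list[Read] = field(default_factory=list)
    paired: bool = False

    def __post_init__(self) -> None:
        if self.paired and len(self.reads) % 2 != 0:
            raise ValueError("paired ReadSet must contain an even number of reads")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> Read:
        return self.reads[i]

    @property
    def n_bases(self) -> int:
        return sum(len(r) for r in self.reads)

    @property
    def modal_read_length(self) -> int:
        """Most common read length (smallest wins a tie, for determinism)."""
        if not self.reads:
            raise ValueError("empty ReadSet has no modal read length")
        counts = Counter(len(r) for r in self.reads)
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        return best[0]

    @property
    def max_read_length(self) -> int:
        return max(len(r) for r in self.reads)


def _open_maybe_gzip(path, mode: str = "rt") -> IO:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    n = 0
    with _open_maybe_gzip(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ at record index {n}: {exc}"
                ) from exc
            yield rec
            n += 1


def read_fastq(path, mate_path=None, paired: bool = False) -> ReadSet:
    """Read one FASTQ file (optionally gzipped) into a ReadSet.

    With ``mate_path``, the two files are interleaved mate-by-mate and the
    result is paired. With ``paired=True`` and a single file, the file is
    taken as already interleaved.
    """
    if mate_path is None:
        reads = [Read(i, s, q) for i, s, q in _iter_fastq(path)]
        return ReadSet(reads, paired=paired)
    reads = []
    it1, it2 = _iter_fastq(path), _iter_fastq(mate_path)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        if r1 is None or r2 is None:
            raise ValueError("mate files contain unequal numbers of records")
        reads.append(Read(*r1))
        reads.append(Read(*r2))
    return ReadSet(reads, paired=True)


def write_fastq(reads: Iterable[Read], path) -> None:
    """Write reads as 4-line FASTQ records; gzip when the path ends in .gz."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for r in reads:
            out.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
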