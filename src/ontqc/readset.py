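"""Read-set statistics, length/quality filtering and coverage subsampling.

Implements the Nx family of contiguity statistics (N50 for reads, N99 for
contigs: the minimum element length such that elements at least that long
cover x% of the total bases), per-read quality as the Phred-scaled mean
error probability, the standard ONT pre-assembly filter (length >= 10 kb,
quality >= Q7), and seeded shuffle-then-fill subsampling to a target
genome coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import LongRead

__all__ = [
    "ReadSetSummary",
    "FilterCounts",
    "nx_value",
    "read_quality",
    "filter_reads",
    "subsample_to_coverage",
    "readset_summary",
]


def nx_value(lengths: Iterable[int], x: float) -> int:
    """Nx of a length multiset: minimum length covering x% of total bases.

    Lengths are sorted descending; the returned value is the length at
    which the running cumulative sum first reaches >= x% of the total.
    """
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("nx_value requires at least one length")
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    cum = np.cumsum(arr)
    threshold = x / 100.0 * cum[-1]
    idx = int(np.searchsorted(cum, threshold, side="left"))
    return int(arr[idx])


def read_quality(quals: Sequence[int]) -> float:
    """Phred-scaled mean error probability: -10*log10(mean 10^(-q/10)).

    This is the convention long-read QC tools report; it down-weights a
    read's score toward its worst bases, unlike an arithmetic mean of Q.
    """
    q = np.asarray(quals, dtype=np.float64)
    if q.size == 0:
        raise ValueError("read_quality requires at least one base")
    mean_p = float(np.mean(np.power(10.0, -q / 10.0)))
    return -10.0 * math.log10(mean_p)


@dataclass
class FilterCounts:
    """Tally filled in as a :func:`filter_reads` stream is consumed."""

    n_kept: int = 0
    n_rejected_length: int = 0
    n_rejected_quality: int = 0

    @property
    def n_input(self) -> int:
        return self.n_kept + self.n_rejected_length + self.n_rejected_quality


def filter_reads(
    reads: Iterable[LongRead],
    min_len: int = 10_000,
    min_q: float = 7.0,
) -> tuple[Iterator[LongRead], FilterCounts]:
    """Keep reads with length >= min_len AND read_quality >= min_q.

    Both thresholds are inclusive; length is checked first. Returns a lazy
    stream of kept reads plus a :class:`FilterCounts` that is populated as
    the stream is consumed.
    """
    counts = FilterCounts()

    def _gen() -> Iterator[LongRead]:
        for read in reads:
            if len(read) < min_len:
                counts.n_rejected_length += 1
            elif read_quality(read.quals) < min_q:
                counts.n_rejected_quality += 1
            else:
                counts.n_kept += 1
                yield read

    return _gen(), counts


def subsample_to_coverage(
    reads: Sequence[LongRead],
    genome_size: int,
    target_cov: float,
    seed: int,
) -> list[LongRead]:
    """Seeded random subset reaching >= target_cov x genome_size bases.

    Reads are shuffled by a seeded permutation and taken in shuffled order
    until the cumulative base count first reaches the target, so the
    target is met exactly once and the result is deterministic for a fixed
    (input order, seed). Raises if the read set cannot reach the target,
    stating the achievable coverage.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if target_cov <= 0:
        raise ValueError("target_cov must be positive")
    reads = list(reads)
    target_bases = target_cov * genome_size
    total = sum(len(r) for r in reads)
    if total < target_bases:
        raise ValueError(
            f"read set holds {total} bases ({total / genome_size:.2f}x); "
            f"cannot reach {target_cov}x of genome size {genome_size}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    picked: list[LongRead] = []
    acc = 0
    for i in order:
        picked.append(reads[i])
        acc += len(reads[i])
        if acc >= target_bases:
            break
    return picked


@dataclass(frozen=True)
class ReadSetSummary:
    """Sequencing-run summary: counts, N50 and mean read quality.

    ``mean_read_q`` is the arithmetic mean over reads of each read's
    error-averaged Q (``q_definition`` records this convention);
    ``mean_base_q_pooled`` is the alternative that pools every base's
    error probability across the whole set before converting back to Q.
    """

    n_reads: int
    total_bases: int
    n50: int
    mean_read_q: float
    mean_base_q_pooled: float
    q_definition: str = field(default="mean_of_per_read_error_averaged_q")


def readset_summary(reads: Iterable[LongRead]) -> ReadSetSummary:
    lengths: list[int] = []
    per_read_q: list[float] = []
    pooled_p_sum = 0.0
    for read in reads:
        lengths.append(len(read))
        q = np.asarray(read.quals, dtype=np.float64)
        p = np.power(10.0, -q / 10.0)
        pooled_p_sum += float(p.sum())
        per_read_q.append(-10.0 * math.log10(float(p.mean())))
    if not lengths:
        raise ValueError("readset_summary requires at least one read")
    total = int(sum(lengths))
    return ReadSetSummary(
        n_reads=len(lengths),
        total_bases=total,
        n50=nx_value(lengths, 50),
        mean_read_q=float(np.mean(per_read_q)),
        mean_base_q_pooled=-10.0 * math.log10(pooled_p_sum / total),
    )
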