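"""Average mapping completeness from terminal clipped bases.

For each read's primary alignment the fraction of the read that was
clipped (soft or hard) at the ends is computed against the full read
length; mapping completeness is one minus the mean of this fraction over
reads. It is an alignment-level measure of how completely an assembly
represents the sequenced reads, complementary to gene-space completeness.

Secondary and supplementary alignments are skipped so each read
contributes exactly one observation; hard-clipped bases count as clipped
and are added back into the denominator, since they belong to the
original read even though the record no longer stores them. Unmapped
reads are excluded from the mean and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqio import AlignmentRecord

__all__ = ["ClipSummary", "IneligibleRecord", "clipped_fraction", "mapping_completeness"]


class IneligibleRecord(ValueError):
    """Record is unmapped, non-primary, or lacks a usable CIGAR."""


@dataclass(frozen=True)
class ClipSummary:
    n_reads_used: int
    mean_clipped_fraction: float
    mapping_completeness: float
    n_unmapped: int
    n_skipped: int


def _eligible(rec: AlignmentRecord, count_supplementary: bool) -> bool:
    if not rec.is_mapped or rec.is_secondary or not rec.has_cigar:
        return False
    if rec.is_supplementary and not count_supplementary:
        return False
    return True


def clipped_fraction(rec: AlignmentRecord, count_hard_clips: bool = True) -> float:
    """Terminal clipped bases divided by the full read length.

    Clip length sums S (and by default H) ops at each end; the full read
    length is the stored query length plus all hard-clipped bases.
    """
    if not rec.is_mapped or rec.is_secondary or rec.is_supplementary:
        raise IneligibleRecord(f"{rec.query_id!r}: not a primary mapped alignment")
    if not rec.has_cigar:
        raise IneligibleRecord(f"{rec.query_id!r}: no CIGAR available")
    clip_ops = "SH" if count_hard_clips else "S"
    ops = rec.cigar
    leading = 0
    for op, n in ops:
        if op in "SH":
            if op in clip_ops:
                leading += n
        else:
            break
    trailing = 0
    for op, n in reversed(ops):
        if op in "SH":
            if op in clip_ops:
                trailing += n
        else:
            break
    full = rec.stored_query_length + (rec.hard_clipped_bases if count_hard_clips else 0)
    if full <= 0:
        raise IneligibleRecord(f"{rec.query_id!r}: zero-length read")
    return (leading + trailing) / full


def mapping_completeness(
    records: Iterable[AlignmentRecord],
    count_hard_clips: bool = True,
    count_supplementary: bool = False,
) -> ClipSummary:
    """Mean clipped fraction over primary mapped reads; completeness = 1 - mean.

    ``count_supplementary=True`` admits supplementary alignments as extra
    observations (off by default: one observation per read). Raises if no
    eligible record is seen.
    """
    n_used = 0
    n_unmapped = 0
    n_skipped = 0
    acc = 0.0
    for rec in records:
        if not rec.is_mapped:
            n_unmapped += 1
            continue
        if not _eligible(rec, count_supplementary):
            n_skipped += 1
            continue
        acc += clipped_fraction(rec, count_hard_clips=count_hard_clips)
        n_used += 1
    if n_used == 0:
        raise ValueError("no eligible primary mapped alignments with CIGARs")
    mean_clip = acc / n_used
    return ClipSummary(
        n_reads_used=n_used,
        mean_clipped_fraction=mean_clip,
        mapping_completeness=1.0 - mean_clip,
        n_unmapped=n_unmapped,
        n_skipped=n_skipped,
    )
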