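"""Coverage-based contig triage for long-read draft assemblies.

A haploid assembly's read-depth profile typically shows (1) a few small
contigs at very high depth (mtDNA, repeat or rRNA contigs), (2) a
plateau of large nuclear contigs sharing a common depth — the 'true
contigs' — and (3) contigs well below the plateau, which are usually
assembly artifacts. This module estimates the plateau depth, applies the
67%-of-plateau artifact cutoff, flags locally elevated depth windows,
and reports the unmapped-read fraction.

Plateau estimation is deliberately simple and robust: the
length-weighted median depth of long contigs anchors a band, and the
length-weighted mean depth of the contigs inside the band is the
plateau. Every constant is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import AlignmentRecord

__all__ = [
    "ContigClass",
    "DepthTrack",
    "contig_mean_depth",
    "plateau_mean",
    "classify_contigs",
    "depth_uniformity",
    "unmapped_fraction",
]


@dataclass(frozen=True)
class ContigClass:
    contig_id: str
    length: int
    mean_depth: float
    label: str  # one of {"true", "artifact", "high_copy"}


@dataclass(frozen=True)
class DepthTrack:
    """Per-bin mean depth along one contig; bins tile the contig."""

    contig_id: str
    bin_size: int
    values: tuple[float, ...]


def contig_mean_depth(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
) -> dict[str, float]:
    """Mean read depth per contig from primary alignments.

    Depth counts reference bases covered by M/=/X ops only; D and N ops
    advance along the reference without contributing read support.
    Contigs with no alignments get depth 0.
    """
    aligned: dict[str, int] = {cid: 0 for cid in contig_lengths}
    for rec in alignments:
        if not rec.is_mapped or rec.is_secondary or rec.is_supplementary:
            continue
        if not rec.has_cigar:
            raise ValueError(f"{rec.query_id!r}: mapped record without CIGAR")
        if rec.target_id not in contig_lengths:
            raise ValueError(f"alignment to unknown contig {rec.target_id!r}")
        aligned[rec.target_id] += sum(n for op, n in rec.cigar if op in "M=X")
    return {cid: aligned[cid] / contig_lengths[cid] for cid in contig_lengths}


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0, side="left"))
    return float(v[idx])


def plateau_mean(
    contigs: Sequence[tuple[int, float]],
    min_len: int = 50_000,
    band: tuple[float, float] = (0.5, 1.5),
) -> float:
    """Length-weighted mean depth of the 'true contig' plateau.

    Long contigs (>= min_len) anchor a length-weighted median depth m;
    the plateau set is the long contigs with depth in [band[0]*m,
    band[1]*m], and the result is their length-weighted mean depth.
    Raises when no long covered contig exists or the band is empty,
    instructing the caller to set the plateau manually.
    """
    rows = [(L, d) for L, d in contigs if L >= min_len and d > 0]
    if not rows:
        raise ValueError(
            f"no contig >= {min_len} bases with positive depth; "
            "pass the plateau depth explicitly"
        )
    lengths = np.array([L for L, _ in rows], dtype=np.float64)
    depths = np.array([d for _, d in rows], dtype=np.float64)
    m = _weighted_median(depths, lengths)
    in_band = (depths >= band[0] * m) & (depths <= band[1] * m)
    if not in_band.any():
        raise ValueError("plateau band is empty; pass the plateau depth explicitly")
    return float(np.average(depths[in_band], weights=lengths[in_band]))


def classify_contigs(
    contigs: Sequence[tuple[str, int, float]],
    plateau: float,
    artifact_frac: float = 0.67,
    high_copy_mult: float = 2.0,
) -> list[ContigClass]:
    """Label contigs against the plateau depth.

    artifact iff depth < artifact_frac * plateau (strict: a contig at
    exactly 67% of the plateau is kept as true); high_copy iff depth >
    high_copy_mult * plateau; otherwise true.
    """
    if plateau <= 0:
        raise ValueError("plateau depth must be positive")
    out: list[ContigClass] = []
    for cid, length, depth in contigs:
        if depth < artifact_frac * plateau:
            label = "artifact"
        elif depth > high_copy_mult * plateau:
            label = "high_copy"
        else:
            label = "true"
        out.append(ContigClass(cid, length, depth, label))
    return out


def depth_uniformity(track: DepthTrack, z_threshold: float = 3.0) -> list[int]:
    """Indices of bins with anomalously elevated depth.

    A bin is flagged when its depth exceeds median + z_threshold * scale,
    where scale is the median absolute deviation times 1.4826 (the
    normal-consistency factor). Median/MAD rather than mean/SD keeps a
    single rRNA-array spike from inflating the scale it is judged
    against. With zero scale (most bins identical), any bin strictly
    above the median is flagged.
    """
    values = np.asarray(track.values, dtype=np.float64)
    if values.size < 10:
        raise ValueError(f"need >= 10 bins, got {values.size}")
    med = float(np.median(values))
    scale = 1.4826 * float(np.median(np.abs(values - med)))
    cutoff = med + z_threshold * scale
    return [i for i, v in enumerate(values) if v > cutoff and v > med]


def unmapped_fraction(alignments: Iterable[AlignmentRecord]) -> float:
    """Percent of reads that failed to map: 100 * unmapped / (unmapped + primary)."""
    n_unmapped = 0
    n_primary = 0
    for rec in alignments:
        if not rec.is_mapped:
            n_unmapped += 1
        elif rec.is_primary:
            n_primary += 1
    total = n_unmapped + n_primary
    if total == 0:
        raise ValueError("no read-level records in alignment stream")
    return 100.0 * n_unmapped / total
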