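"""Sliding-window telomere-repeat detection and per-contig end classification.

Filamentous-fungal telomeres are tandem arrays of TTAGGG; its reverse
complement CCCTAA marks the opposite strand, so the two motifs are
treated as one telomeric signal. Only 100% identity matches count (an N
never matches). A chromosome-level contig is expected to show an
increased motif count at both termini and few matches internally.

The end classification ("is this terminus telomeric?") uses an explicit
copy threshold inside a terminal window. A fully repeat-covered 100 b
window holds 16 motif copies while random sequence yields under one
exact copy per kilobase per strand, so the defaults (>= 5 copies within
the terminal 1 kb) separate the two regimes by an order of magnitude in
either direction; both are tunable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import Contig

__all__ = [
    "TELOMERE_MOTIFS",
    "WindowTrack",
    "TelomereReport",
    "ContigTelomereRow",
    "find_motif_occurrences",
    "scan_windows",
    "classify_ends",
    "assembly_telomere_report",
]

TELOMERE_MOTIFS: tuple[str, ...] = ("TTAGGG", "CCCTAA")


@dataclass(frozen=True)
class WindowTrack:
    """Per-contig sliding-window motif counts (0-based half-open windows)."""

    contig_id: str
    bin_size: int
    step: int
    windows: tuple[tuple[int, int, int], ...]  # (start, end, motif_count)

    def to_bedgraph_lines(self) -> list[str]:
        return [f"{self.contig_id}\t{s}\t{e}\t{c}" for s, e, c in self.windows]


@dataclass(frozen=True)
class ContigTelomereRow:
    contig_id: str
    length: int
    n_tel_ends: int
    excluded: bool


@dataclass(frozen=True)
class TelomereReport:
    rows: tuple[ContigTelomereRow, ...]
    total_tel_regions: int
    n_both_ends: int
    n_one_end: int
    n_no_ends: int


def find_motif_occurrences(
    seq: str,
    motifs: Sequence[str] = TELOMERE_MOTIFS,
) -> list[tuple[int, str]]:
    """All exact occurrences of each motif, overlapping starts permitted.

    Matching is case-insensitive via upcasing; N never matches because
    only perfect-identity hits count as telomeric repeats.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    seq = seq.upper()
    hits: list[tuple[int, str]] = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            hits.append((start, motif))
            start = seq.find(motif, start + 1)
    hits.sort()
    return hits


def scan_windows(contig: Contig, bin_size: int = 100, step: int = 25) -> WindowTrack:
    """Sliding-window motif counts at starts 0, step, 2*step, ...

    A motif counts toward a window only when it lies fully inside the
    half-open window interval; the final window is truncated at the
    contig end.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if bin_size < max(len(m) for m in TELOMERE_MOTIFS):
        raise ValueError("bin_size must be at least the motif length")
    length = len(contig)
    hits = find_motif_occurrences(contig.bases)
    starts = [s for s, _ in hits]
    ends = [s + len(m) for s, m in hits]
    windows: list[tuple[int, int, int]] = []
    w = 0
    while True:
        end = min(w + bin_size, length)
        count = sum(1 for s, e in zip(starts, ends) if s >= w and e <= end)
        windows.append((w, end, count))
        if end >= length:
            break
        w += step
    return WindowTrack(contig.contig_id, bin_size, step, tuple(windows))


def _count_in(hits: list[tuple[int, str]], lo: int, hi: int) -> int:
    return sum(1 for s, m in hits if s >= lo and s + len(m) <= hi)


def classify_ends(
    contig: Contig,
    end_window: int = 1000,
    min_copies: int = 5,
    motifs: Sequence[str] = TELOMERE_MOTIFS,
) -> int:
    """Number of telomeric termini (0, 1 or 2) of a contig.

    A terminus is telomeric iff at least ``min_copies`` exact motif
    occurrences lie fully within its terminal ``end_window`` bases. On a
    contig shorter than ``2 * end_window`` the two end regions overlap;
    both are still evaluated.
    """
    length = len(contig)
    hits = find_motif_occurrences(contig.bases, motifs)
    left = _count_in(hits, 0, min(end_window, length))
    right = _count_in(hits, max(0, length - end_window), length)
    return int(left >= min_copies) + int(right >= min_copies)


def assembly_telomere_report(
    contigs: Iterable[Contig],
    exclude_ids: set[str] | None = None,
    end_window: int = 1000,
    min_copies: int = 5,
) -> TelomereReport:
    """Classify every contig's ends and tally assembly-level totals.

    ``exclude_ids`` removes contigs (typically mtDNA or pure-rRNA contigs
    identified by external annotation) from the totals; they still appear
    in the per-contig rows with the excluded flag set. Unknown ids in
    ``exclude_ids`` trigger a warning.
    """
    exclude_ids = set(exclude_ids or ())
    rows: list[ContigTelomereRow] = []
    seen_ids: set[str] = set()
    both = one = none = 0
    for contig in contigs:
        seen_ids.add(contig.contig_id)
        excluded = contig.contig_id in exclude_ids
        n_ends = classify_ends(contig, end_window=end_window, min_copies=min_copies)
        rows.append(ContigTelomereRow(contig.contig_id, len(contig), n_ends, excluded))
        if not excluded:
            if n_ends == 2:
                both += 1
            elif n_ends == 1:
                one += 1
            else:
                none += 1
    if not rows:
        raise ValueError("empty assembly")
    unknown = exclude_ids - seen_ids
    if unknown:
        warnings.warn(f"exclude ids not found in assembly: {sorted(unknown)}")
    return TelomereReport(
        rows=tuple(rows),
        total_tel_regions=2 * both + one,
        n_both_ends=both,
        n_one_end=one,
        n_no_ends=none,
    )
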