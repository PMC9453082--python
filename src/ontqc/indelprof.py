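"""Homopolymeric vs. random indel profiling of gene-scale sequences.

Nanopore consensus sequences characteristically acquire small insertions
and deletions inside homopolymer runs, and less often elsewhere. Given a
trusted reference gene and its copy extracted from an assembly, this
module aligns the pair globally, extracts every indel as a maximal gap
run, and classifies each as homopolymeric (a single repeated base whose
combined run with the flanking reference reaches a minimum length) or
random. Counting both classes across a panel of conserved single-copy
genes tracks how consensus accuracy responds to sequencing depth and
polishing.

The aligner is a Gotoh-style global affine-gap dynamic program. A gap of
length L costs ``gap_open + L * gap_extend``, so the default scoring
(+1 match, -2 mismatch, -4 open, -2 extend) prefers one multi-base gap
over the same bases scattered across several gaps — the shape real
assembly-vs-gene indels take. Traceback tie-breaking is fixed (diagonal,
then gap in the assembly sequence, then gap in the reference) so results
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PairwiseAlignment",
    "IndelEvent",
    "IndelCounts",
    "global_align",
    "extract_indels",
    "is_homopolymeric",
    "indel_error_counts",
]

_NEG = np.int64(-(2**40))  # effectively -infinity, safe from int64 overflow


@dataclass(frozen=True)
class PairwiseAlignment:
    """Global alignment of A (reference) and B (assembly), gap char '-'."""

    aligned_a: str
    aligned_b: str
    score: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


@dataclass(frozen=True)
class IndelEvent:
    """One maximal indel relative to sequence A (the reference).

    ``ref_pos`` is 0-based in ungapped A coordinates: for an insertion it
    is the position before which the bases are inserted; for a deletion
    it is the position of the first deleted base.
    """

    kind: str  # "insertion" | "deletion"
    ref_pos: int
    seq: str
    homopolymeric: bool = False


def global_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -2,
) -> PairwiseAlignment:
    """Optimal global alignment of a and b under affine gap scoring.

    Gap cost model: a gap of length L scores ``gap_open + L*gap_extend``
    (set ``gap_open=0`` for linear gaps). Ties on traceback prefer the
    diagonal, then a gap in b (deletion from A's view), then a gap in a.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    op, ex = np.int64(gap_open), np.int64(gap_extend)

    # Row-wise DP. Per row we keep H (best), F (gap-in-b, vertical) and
    # compute E (gap-in-a, horizontal) by a max-plus prefix scan:
    # E[j] = op + ex*j + max_{k<j}(src[k] - ex*k), which equals the
    # sequential Gotoh recurrence because re-opening out of E is always
    # dominated by extending E.
    j_idx = np.arange(m + 1, dtype=np.int64)
    H_prev = np.empty(m + 1, dtype=np.int64)
    H_prev[0] = 0
    H_prev[1:] = op + ex * j_idx[1:]
    F_prev = np.full(m + 1, _NEG, dtype=np.int64)

    # traceback bits: 0-1 = H source (0 diag, 1 F, 2 E); 2 = E extends; 3 = F extends
    tb = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb[0, 1:] |= 2
    tb[0, 2:] |= 4
    tb[1:, 0] |= 1
    if n >= 2:
        tb[2:, 0] |= 8

    for i in range(1, n + 1):
        f_ext = F_prev >= H_prev + op
        F_row = np.where(f_ext, F_prev, H_prev + op) + ex

        sub = np.where(b_arr == ord(a[i - 1]), np.int64(match), np.int64(mismatch))
        diag = H_prev[:-1] + sub

        h0 = np.int64(op + ex * i)  # H at column 0 of this row
        G = np.maximum(diag, F_row[1:])
        src = np.empty(m, dtype=np.int64)
        src[0] = h0
        if m > 1:
            src[1:] = G[:-1]
        E_row = np.empty(m + 1, dtype=np.int64)
        E_row[0] = _NEG
        E_row[1:] = op + ex * j_idx[1:] + np.maximum.accumulate(src - ex * j_idx[:-1])

        H_row = np.empty(m + 1, dtype=np.int64)
        H_row[0] = h0
        H_row[1:] = np.maximum(G, E_row[1:])

        ptr = np.full(m, 2, dtype=np.uint8)  # default E
        ptr[H_row[1:] == F_row[1:]] = 1
        ptr[H_row[1:] == diag] = 0  # diagonal wins ties
        e_ext = np.zeros(m + 1, dtype=bool)
        e_ext[2:] = E_row[2:] == E_row[1:-1] + ex  # prefer extending on ties
        tb[i, 1:] = ptr | (e_ext[1:].astype(np.uint8) << 2) | (f_ext[1:].astype(np.uint8) << 3)
        tb[i, 0] = 1 | (np.uint8(8) if f_ext[0] or i == 1 else np.uint8(0))

        H_prev, F_prev = H_row, F_row

    score = int(H_prev[m])

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = n, m, "H"
    while i > 0 or j > 0:
        if i == 0:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            continue
        if j == 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        cell = tb[i, j]
        if state == "H":
            choice = cell & 3
            if choice == 0:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif choice == 1:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            ext = bool(cell & 8)
            i -= 1
            state = "F" if ext else "H"
        else:  # E
            out_a.append("-")
            out_b.append(b[j - 1])
            ext = bool(cell & 4)
            j -= 1
            state = "E" if ext else "H"
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


def extract_indels(aln: PairwiseAlignment) -> list[IndelEvent]:
    """Maximal gap runs of an alignment as indel events in A coordinates."""
    events: list[IndelEvent] = []
    ref_pos = 0
    k = 0
    cols = len(aln.aligned_a)
    while k < cols:
        ca, cb = aln.aligned_a[k], aln.aligned_b[k]
        if ca == "-" and cb == "-":
            raise ValueError(f"column {k}: gap in both rows")
        if ca == "-":
            start = k
            while k < cols and aln.aligned_a[k] == "-":
                k += 1
            events.append(IndelEvent("insertion", ref_pos, aln.aligned_b[start:k]))
        elif cb == "-":
            start_ref = ref_pos
            start = k
            while k < cols and aln.aligned_b[k] == "-":
                ref_pos += 1
                k += 1
            events.append(IndelEvent("deletion", start_ref, aln.aligned_a[start:k]))
        else:
            ref_pos += 1
            k += 1
    return events


def _run_left(ref: str, pos: int, base: str) -> int:
    n = 0
    while pos >= 0 and ref[pos] == base:
        n += 1
        pos -= 1
    return n


def _run_right(ref: str, pos: int, base: str) -> int:
    n = 0
    while pos < len(ref) and ref[pos] == base:
        n += 1
        pos += 1
    return n


def is_homopolymeric(event: IndelEvent, ref: str, min_run: int = 3) -> bool:
    """True iff the event is a single-base indel inside a homopolymer run.

    The event bases must all be one base b, and the maximal run of b in
    the reference touching the event position, combined with the event
    bases themselves, must reach ``min_run``.
    """
    bases = set(event.seq)
    if len(bases) != 1:
        return False
    base = event.seq[0]
    k = len(event.seq)
    if event.kind == "deletion":
        run = k + _run_left(ref, event.ref_pos - 1, base) + _run_right(ref, event.ref_pos + k, base)
    else:
        run = k + _run_left(ref, event.ref_pos - 1, base) + _run_right(ref, event.ref_pos, base)
    return run >= min_run


@dataclass(frozen=True)
class IndelCounts:
    per_gene: tuple[tuple[str, int, int], ...]  # (gene_id, n_homopolymeric, n_random)
    n_homopolymeric: int
    n_random: int

    @property
    def n_total(self) -> int:
        return self.n_homopolymeric + self.n_random


def indel_error_counts(
    gene_pairs: Sequence[tuple[str, str, str]],
    min_run: int = 3,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -2,
) -> IndelCounts:
    """Align (gene_id, reference, assembly) pairs and tally indel classes.

    Insertions/deletions are polarized relative to the reference gene.
    """
    if not gene_pairs:
        raise ValueError("at least one gene pair is required")
    rows: list[tuple[str, int, int]] = []
    total_h = total_r = 0
    for gene_id, ref, asm in gene_pairs:
        if not ref or not asm:
            raise ValueError(f"gene {gene_id!r}: empty sequence")
        aln = global_align(
            ref, asm, match=match, mismatch=mismatch, gap_open=gap_open, gap_extend=gap_extend
        )
        n_h = n_r = 0
        ref_upper = ref.upper()
        for event in extract_indels(aln):
            if is_homopolymeric(event, ref_upper, min_run=min_run):
                n_h += 1
            else:
                n_r += 1
        rows.append((gene_id, n_h, n_r))
        total_h += n_h
        total_r += n_r
    return IndelCounts(tuple(rows), total_h, total_r)
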