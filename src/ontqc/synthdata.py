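"""Seeded synthetic fixtures with planted ground truth.

Generators for every input the analysis modules consume: read sets with
log-normal lengths and controlled quality, assemblies with exact
telomere-repeat arrays planted at chosen ends, alignment sets with known
clip fractions and exact depth tilings, and gene pairs with planted
homopolymeric/random indels. Each generator is a pure function of its
arguments plus a seed, so fixtures are byte-stable across runs; no
global random state is touched.

These fixtures emulate the statistical regime of real ONT fungal runs
(tens-of-kilobase reads around Q12, ~30 Mb haploid assemblies at a
~100x coverage plateau) but not ONT error processes themselves: there is
no quality-by-position structure, no chimeras, and planted indels are
isolated by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .seqio import AlignmentRecord, Contig, LongRead, cigar_to_string

__all__ = [
    "SimTruth",
    "simulate_reads",
    "make_assembly_with_telomeres",
    "simulate_alignments",
    "tile_contig_alignments",
    "plant_indels",
    "random_sequence",
    "alignments_to_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
TELOMERE_FWD = "TTAGGG"
TELOMERE_REV = "CCCTAA"


@dataclass(frozen=True)
class SimTruth:
    """Planted parameters of a fixture, plus the seed that produced it."""

    seed: int
    params: dict[str, Any] = field(default_factory=dict)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence."""
    if length < 0:
        raise ValueError("length must be non-negative")
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def simulate_reads(
    n: int,
    log_len_mean: float = 9.7,
    log_len_sd: float = 0.6,
    q_mean: float = 12.0,
    q_sd: float = 1.0,
    seed: int = 0,
    base_sd: float = 0.0,
) -> tuple[list[LongRead], SimTruth]:
    """Reads with log-normal lengths and per-read mean quality.

    Lengths are log-normal (rounded, minimum 1); the defaults give a
    median around 16 kb, the post-filter regime of an ONT fungal run.
    Each read draws a mean quality from Normal(q_mean, q_sd); per-base
    Phred scores are drawn around that mean with spread ``base_sd``
    (default 0: every base carries the read mean, rounded) and clamped
    to [1, 50].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if log_len_sd < 0 or q_sd < 0 or base_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if not np.isfinite([log_len_mean, log_len_sd, q_mean, q_sd]).all():
        raise ValueError("parameters must be finite")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(1, np.rint(rng.lognormal(log_len_mean, log_len_sd, n))).astype(int)
    read_means = rng.normal(q_mean, q_sd, n) if q_sd > 0 else np.full(n, float(q_mean))
    reads: list[LongRead] = []
    for i in range(n):
        L = int(lengths[i])
        bases = random_sequence(L, rng)
        if base_sd > 0:
            q = np.rint(rng.normal(read_means[i], base_sd, L))
        else:
            q = np.full(L, np.rint(read_means[i]))
        quals = tuple(int(v) for v in np.clip(q, 1, 50))
        reads.append(LongRead(f"simread_{i}", bases, quals))
    truth = SimTruth(
        seed,
        {
            "n": n,
            "log_len_mean": log_len_mean,
            "log_len_sd": log_len_sd,
            "q_mean": q_mean,
            "q_sd": q_sd,
            "base_sd": base_sd,
            "lengths": [int(v) for v in lengths],
        },
    )
    return reads, truth


def make_assembly_with_telomeres(
    contig_specs: Sequence[tuple[int, int, int]],
    seed: int = 0,
) -> tuple[list[Contig], SimTruth]:
    """Contigs with exact telomere-motif arrays planted at the ends.

    Each spec is (length, left_copies, right_copies): the contig starts
    with ``left_copies`` tandem TTAGGG and ends with ``right_copies``
    tandem CCCTAA, with uniform random interior.
    """
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    end_map: dict[str, tuple[int, int]] = {}
    for i, (length, left, right) in enumerate(contig_specs):
        motif_len = 6 * (left + right)
        if length < max(1, 2 * motif_len):
            raise ValueError(
                f"contig spec {i}: length {length} too short for "
                f"{left}+{right} planted motif copies"
            )
        interior = random_sequence(length - motif_len, rng)
        seq = TELOMERE_FWD * left + interior + TELOMERE_REV * right
        cid = f"simcontig_{i}"
        contigs.append(Contig(cid, seq))
        end_map[cid] = (left, right)
    truth = SimTruth(seed, {"end_map": end_map, "specs": [tuple(s) for s in contig_specs]})
    return contigs, truth


def simulate_alignments(
    n_reads: int,
    read_length: int = 10_000,
    mean_clip_frac: float = 0.1,
    clip_concentration: float = 20.0,
    target_id: str = "simcontig_0",
    target_length: int | None = None,
    n_unmapped: int = 0,
    hard_clip_frac: float = 0.0,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Primary alignments with a planted mean terminal clip fraction.

    Per-read clip fractions are Beta-distributed with mean
    ``mean_clip_frac`` (zero variance when ``mean_clip_frac`` is 0) and
    are realized as xS yM zS CIGARs, the left/right split uniform. A
    fraction ``hard_clip_frac`` of clipped reads use H instead of S ops.
    ``n_unmapped`` unmapped records are appended.
    """
    if not 0 <= mean_clip_frac < 1:
        raise ValueError("mean_clip_frac must be in [0, 1)")
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    rng = np.random.default_rng(seed)
    if mean_clip_frac > 0:
        a = clip_concentration * mean_clip_frac
        b = clip_concentration * (1 - mean_clip_frac)
        fracs = rng.beta(a, b, n_reads)
    else:
        fracs = np.zeros(n_reads)
    if target_length is None:
        target_length = read_length * 2
    records: list[AlignmentRecord] = []
    planted: list[float] = []
    for i in range(n_reads):
        clip_total = int(np.rint(fracs[i] * read_length))
        clip_total = min(clip_total, read_length - 1)
        left = int(rng.integers(0, clip_total + 1))
        right = clip_total - left
        matched = read_length - clip_total
        hard = rng.random() < hard_clip_frac
        clip_op = "H" if hard else "S"
        cigar: list[tuple[str, int]] = []
        if left:
            cigar.append((clip_op, left))
        cigar.append(("M", matched))
        if right:
            cigar.append((clip_op, right))
        stored = read_length - (clip_total if hard else 0)
        start = int(rng.integers(0, max(1, target_length - matched + 1)))
        records.append(
            AlignmentRecord(
                query_id=f"simaln_{i}",
                is_mapped=True,
                target_id=target_id,
                target_start=start,
                cigar=tuple(cigar),
                stored_query_length=stored,
            )
        )
        planted.append(clip_total / read_length)
    for i in range(n_unmapped):
        records.append(AlignmentRecord(query_id=f"simunmapped_{i}", is_mapped=False))
    truth = SimTruth(
        seed,
        {
            "mean_clip_frac": mean_clip_frac,
            "realized_mean_clip_frac": float(np.mean(planted)) if planted else 0.0,
            "n_reads": n_reads,
            "n_unmapped": n_unmapped,
            "target_length": target_length,
        },
    )
    return records, truth


def tile_contig_alignments(
    contig_lengths: dict[str, int],
    depths: dict[str, int],
    seed: int = 0,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Exact full-length tilings: each contig gets depth d from d spanning reads.

    Every record is a full-length match (CIGAR ``LM``), so the planted
    per-contig mean depth is hit exactly — the fixture for integer-depth
    checks of the coverage classifier.
    """
    records: list[AlignmentRecord] = []
    for cid, length in contig_lengths.items():
        d = depths.get(cid, 0)
        for k in range(d):
            records.append(
                AlignmentRecord(
                    query_id=f"tile_{cid}_{k}",
                    is_mapped=True,
                    target_id=cid,
                    target_start=0,
                    cigar=(("M", length),),
                    stored_query_length=length,
                )
            )
    truth = SimTruth(seed, {"depths": dict(depths), "contig_lengths": dict(contig_lengths)})
    return records, truth


def _candidate_positions(seq: str, min_run: int) -> tuple[list[int], list[int]]:
    """(homopolymer-run start indices with run >= min_run, run-free positions)."""
    n = len(seq)
    run_starts: list[int] = []
    in_run = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            run_starts.append(i)
            in_run[i:j] = True
        i = j
    # run-free: position p such that seq[p-2:p+4] holds no run >= min_run-1
    free = [
        p
        for p in range(4, n - 6)
        if not in_run[max(0, p - 3) : p + 5].any()
    ]
    return run_starts, free


def plant_indels(
    seq: str,
    n_homo: int,
    n_random: int,
    seed: int = 0,
    min_separation: int = 10,
) -> tuple[str, SimTruth]:
    """Mutate a sequence with isolated homopolymeric and random indels.

    Homopolymeric events are single-base insertions or deletions inside
    homopolymer runs of length >= 3; random events are 2-3 b
    insertions/deletions of mixed bases placed away from any run, so the
    classifier's verdict is unambiguous. Events are separated by at
    least ``min_separation`` bases. Raises when the sequence cannot host
    the requested events.
    """
    seq = seq.upper()
    rng = np.random.default_rng(seed)
    run_starts, free = _candidate_positions(seq, 3)
    events: list[dict[str, Any]] = []  # position in original coords
    taken: list[int] = []

    def _far_enough(p: int) -> bool:
        return all(abs(p - t) >= min_separation for t in taken)

    homo_pool = [p for p in rng.permutation(len(run_starts))]
    placed = 0
    for idx in homo_pool:
        if placed == n_homo:
            break
        p = run_starts[idx]
        if _far_enough(p):
            base = seq[p]
            if rng.random() < 0.5:
                events.append({"pos": p, "kind": "deletion", "seq": base, "cls": "homo"})
            else:
                events.append({"pos": p, "kind": "insertion", "seq": base, "cls": "homo"})
            taken.append(p)
            placed += 1
    if placed < n_homo:
        raise ValueError(
            f"sequence holds only {placed} usable homopolymer runs "
            f"(>=3, separated by {min_separation}); {n_homo} requested"
        )
    rand_pool = [p for p in rng.permutation(len(free))]
    placed = 0
    for idx in rand_pool:
        if placed == n_random:
            break
        p = free[idx]
        if not _far_enough(p):
            continue
        size = int(rng.integers(2, 4))
        if rng.random() < 0.5:
            piece = seq[p : p + size]
            if len(set(piece)) < 2:
                continue
            events.append({"pos": p, "kind": "deletion", "seq": piece, "cls": "random"})
        else:
            # mixed-base insert that extends no flanking run
            choices = [b for b in "ACGT" if b != seq[p - 1] and b != seq[p]]
            first = choices[int(rng.integers(0, len(choices)))]
            second = [b for b in "ACGT" if b != first][int(rng.integers(0, 3))]
            piece = (first + second)[:size] if size == 2 else first + second + first
            events.append({"pos": p, "kind": "insertion", "seq": piece, "cls": "random"})
        taken.append(p)
        placed += 1
    if placed < n_random:
        raise ValueError(
            f"could not place {n_random} random indels with separation {min_separation}"
        )

    mutated = seq
    for ev in sorted(events, key=lambda e: e["pos"], reverse=True):
        p = ev["pos"]
        if ev["kind"] == "deletion":
            mutated = mutated[:p] + mutated[p + len(ev["seq"]) :]
        else:
            mutated = mutated[:p] + ev["seq"] + mutated[p:]
    truth = SimTruth(
        seed,
        {
            "n_homo": n_homo,
            "n_random": n_random,
            "events": sorted(events, key=lambda e: e["pos"]),
        },
    )
    return mutated, truth


def alignments_to_sam(
    records: Sequence[AlignmentRecord],
    contig_lengths: dict[str, int],
    rng: np.random.Generator | None = None,
) -> str:
    """Render records as SAM text with @SQ headers, synthesizing SEQ/QUAL.

    Sequences are random (or '*' when no generator is given); CIGARs,
    flags and coordinates carry the planted truth, which is all the
    downstream statistics read.
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for cid, length in contig_lengths.items():
        lines.append(f"@SQ\tSN:{cid}\tLN:{length}")
    for rec in records:
        if rec.is_mapped:
            flag = 0
            if rec.is_secondary:
                flag |= 256
            if rec.is_supplementary:
                flag |= 2048
            seq = (
                random_sequence(rec.stored_query_length, rng)
                if rng is not None
                else "*"
            )
            qual = "I" * rec.stored_query_length if rng is not None else "*"
            lines.append(
                "\t".join(
                    [
                        rec.query_id,
                        str(flag),
                        rec.target_id or "*",
                        str(rec.target_start + 1),
                        "60",
                        cigar_to_string(rec.cigar),
                        "*",
                        "0",
                        "0",
                        seq,
                        qual,
                    ]
                )
            )
        else:
            seq = random_sequence(100, rng) if rng is not None else "*"
            qual = "I" * 100 if rng is not None else "*"
            lines.append(
                "\t".join([rec.query_id, "4", "*", "0", "0", "*", "*", "0", "0", seq, qual])
            )
    return "\n".join(lines) + "\n"
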