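"""Readers/writers for FASTQ, FASTA, SAM/BAM and PAF, plus CIGAR parsing.

All coordinates are 0-based, half-open. Phred encoding is fixed at the
Sanger offset (ASCII-33); ONT basecallers emit nothing else. Lowercase
bases are upcased on input and anything outside ``{A,C,G,T,N}`` is
rejected, because downstream motif matching is exact.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "LongRead",
    "Contig",
    "AlignmentRecord",
    "ParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "parse_cigar",
    "cigar_to_string",
    "read_alignments",
]

_VALID_BASES = frozenset("ACGTN")
_CIGAR_OPS = frozenset("MIDNSHP=X")
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class ParseError(ValueError):
    """Malformed input file or record."""


def _clean_bases(raw: str, where: str) -> str:
    bases = raw.upper()
    bad = set(bases) - _VALID_BASES
    if bad:
        raise ParseError(f"{where}: invalid characters {sorted(bad)} in sequence")
    return bases


@dataclass(frozen=True)
class LongRead:
    """One sequencing read: id, bases, per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.bases) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Contig:
    """One assembly contig."""

    contig_id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        if len(self.bases) < 1:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-contig alignment, normalized across SAM/BAM/PAF.

    ``stored_query_length`` counts the bases present in the record itself,
    i.e. it excludes hard-clipped bases; the original read length is
    recovered by adding the H op lengths back (see :mod:`ontqc.clipstat`).
    A mapped record whose CIGAR was ``*`` is retained with an empty
    ``cigar`` and is unusable for clip/depth statistics.
    """

    query_id: str
    is_mapped: bool
    is_primary: bool = True
    is_secondary: bool = False
    is_supplementary: bool = False
    target_id: str | None = None
    target_start: int = 0
    cigar: tuple[tuple[str, int], ...] = field(default=())
    stored_query_length: int = 0

    def __post_init__(self) -> None:
        if self.is_mapped and self.target_id is None:
            raise ValueError(f"{self.query_id!r}: mapped record without target")
        if self.cigar:
            _validate_clip_placement(self.cigar)
            qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if qlen != self.stored_query_length:
                raise ValueError(
                    f"{self.query_id!r}: CIGAR consumes {qlen} query bases but "
                    f"stored_query_length is {self.stored_query_length}"
                )

    @property
    def has_cigar(self) -> bool:
        return bool(self.cigar)

    @property
    def hard_clipped_bases(self) -> int:
        return sum(n for op, n in self.cigar if op == "H")

    @property
    def full_query_length(self) -> int:
        """Original read length: stored bases plus hard-clipped bases."""
        return self.stored_query_length + self.hard_clipped_bases

    def reference_span(self) -> int:
        """Reference bases consumed by this alignment (M/D/N/=/X)."""
        return sum(n for op, n in self.cigar if op in _REF_OPS)


# ---------------------------------------------------------------------------
# FASTQ


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[LongRead]:
    """Stream FASTQ records (plain or gzip, detected by magic bytes).

    Phred scores are ASCII-33. Raises :class:`ParseError` naming the
    1-based record index on any malformed record.
    """
    with _open_maybe_gzip(path) as handle:
        idx = 0
        while True:
            header = handle.readline()
            if not header:
                return
            if header.strip() == "":
                continue
            idx += 1
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise ParseError(f"record {idx}: truncated FASTQ record")
            header = header.rstrip("\n")
            seq = seq.strip()
            qual = qual.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"record {idx}: header does not start with '@'")
            if not plus.startswith("+"):
                raise ParseError(f"record {idx}: separator line does not start with '+'")
            if len(seq) != len(qual):
                raise ParseError(
                    f"record {idx}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            if not read_id:
                raise ParseError(f"record {idx}: empty read id")
            quals = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 for q in quals):
                raise ParseError(f"record {idx}: quality character below ASCII 33")
            yield LongRead(read_id, _clean_bases(seq, f"record {idx}"), quals)


def write_fastq(reads: Iterable[LongRead], path: str | Path) -> int:
    """Write reads as 4-line FASTQ (gzip if the path ends in .gz); returns count."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Iterator[Contig]:
    """Stream FASTA records; id is the header token before the first whitespace.

    Duplicate ids and empty sequences raise :class:`ParseError`.
    """
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            contig_id = header.split()[0] if header.split() else ""
            if not contig_id:
                raise ParseError("FASTA record with empty id")
            if contig_id in seen:
                raise ParseError(f"duplicate contig id {contig_id!r}")
            seen.add(contig_id)
            if not seq:
                raise ParseError(f"contig {contig_id!r}: empty sequence")
            yield Contig(contig_id, _clean_bases(seq, f"contig {contig_id!r}"))


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> int:
    n = 0
    with open(path, "wt") as out:
        for contig in contigs:
            out.write(f">{contig.contig_id}\n")
            for i in range(0, len(contig.bases), width):
                out.write(contig.bases[i : i + width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# CIGAR


def _validate_clip_placement(ops: tuple[tuple[str, int], ...]) -> None:
    # H may appear only as first/last op; S only adjacent to the ends or to
    # a terminal H. Equivalently: strip terminal H, then strip terminal S,
    # and no clip op may remain.
    inner = list(ops)
    if inner and inner[0][0] == "H":
        inner = inner[1:]
    if inner and inner[-1][0] == "H":
        inner = inner[:-1]
    if inner and inner[0][0] == "S":
        inner = inner[1:]
    if inner and inner[-1][0] == "S":
        inner = inner[:-1]
    for op, _ in inner:
        if op in "SH":
            raise ParseError(f"clip op {op} in CIGAR interior: {cigar_to_string(ops)}")


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string into ``((op, length), ...)``; ``"*"`` -> ``()``.

    Rejects unknown op letters, zero lengths, and interior clip ops.
    """
    if text == "*":
        return ()
    if not text:
        raise ParseError("empty CIGAR string")
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ParseError(f"malformed CIGAR {text!r} at offset {pos}")
        n = int(m.group(1))
        if n == 0:
            raise ParseError(f"zero-length op in CIGAR {text!r}")
        ops.append((m.group(2), n))
        pos = m.end()
    if pos != len(text):
        raise ParseError(f"malformed CIGAR {text!r} at offset {pos}")
    result = tuple(ops)
    _validate_clip_placement(result)
    return result


def cigar_to_string(ops: Iterable[tuple[str, int]]) -> str:
    ops = tuple(ops)
    if not ops:
        return "*"
    return "".join(f"{n}{op}" for op, n in ops)


# ---------------------------------------------------------------------------
# Alignments

_PYSAM_OPS = "MIDNSHP=X"


def _from_pysam(rec: pysam.AlignedSegment, sam: pysam.AlignmentFile) -> AlignmentRecord:
    mapped = not rec.is_unmapped
    cigar: tuple[tuple[str, int], ...] = ()
    if mapped and rec.cigartuples:
        cigar = tuple((_PYSAM_OPS[op], n) for op, n in rec.cigartuples)
    stored = rec.query_length
    if stored == 0 and cigar:
        stored = sum(n for op, n in cigar if op in _QUERY_OPS)
    return AlignmentRecord(
        query_id=rec.query_name or "",
        is_mapped=mapped,
        is_primary=mapped and not (rec.is_secondary or rec.is_supplementary),
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        target_id=sam.get_reference_name(rec.reference_id) if mapped else None,
        target_start=rec.reference_start if mapped else 0,
        cigar=cigar,
        stored_query_length=stored if mapped else (rec.query_length or 0),
    )


def _paf_records(path: str | Path) -> Iterator[AlignmentRecord]:
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"PAF line {lineno}: fewer than 12 columns")
            qname, qlen, qstart, qend = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
            tname, tstart = fields[5], int(fields[7])
            tags = dict(
                (f.split(":", 2)[0], f.split(":", 2)[2]) for f in fields[12:] if f.count(":") >= 2
            )
            cg = tags.get("cg")
            tp = tags.get("tp", "P")
            core = parse_cigar(cg) if cg is not None else ()
            # PAF CIGARs cover qstart..qend only: synthesize the terminal
            # clips so one AlignmentRecord dialect serves clip/depth code.
            ops: list[tuple[str, int]] = []
            if core:
                if qstart > 0:
                    ops.append(("S", qstart))
                ops.extend(core)
                if qlen - qend > 0:
                    ops.append(("S", qlen - qend))
            yield AlignmentRecord(
                query_id=qname,
                is_mapped=True,
                is_primary=tp == "P",
                is_secondary=tp == "S",
                is_supplementary=tp == "I",
                target_id=tname,
                target_start=tstart,
                cigar=tuple(ops),
                stored_query_length=qlen if ops else qlen,
            )


def read_alignments(path: str | Path, fmt: str | None = None) -> Iterator[AlignmentRecord]:
    """Stream alignments from SAM, BAM or PAF as :class:`AlignmentRecord`.

    ``fmt`` is one of ``{"sam", "bam", "paf"}``; if omitted it is inferred
    from the file extension. PAF records without a ``cg:Z:`` CIGAR tag are
    yielded with an empty CIGAR; downstream operations that require a CIGAR
    raise an explicit error rather than skipping them silently.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "paf":
        yield from _paf_records(path)
        return
    if fmt not in ("sam", "bam"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    mode = "rb" if fmt == "bam" else "r"
    save = pysam.set_verbosity(0)  # silence missing-index chatter
    try:
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
            for rec in sam.fetch(until_eof=True):
                yield _from_pysam(rec, sam)
    finally:
        pysam.set_verbosity(save)
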