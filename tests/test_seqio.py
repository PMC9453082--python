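"""Format readers, CIGAR parsing, and record invariants."""

import gzip

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ontqc.seqio import (
    AlignmentRecord,
    Contig,
    LongRead,
    ParseError,
    cigar_to_string,
    parse_cigar,
    read_alignments,
    read_fasta,
    read_fastq,
    write_fasta,
    write_fastq,
)


class TestFastq:
    def test_reads_records_in_order_with_sanger_offset(self, fastq_file):
        reads = list(read_fastq(fastq_file))
        assert [r.read_id for r in reads] == ["r1", "r2", "r3"]
        assert reads[0].bases == "ACGT"
        assert reads[0].quals == (40, 40, 40, 40)
        assert reads[1].quals == (0,) * 10

    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        assert list(read_fastq(path)) == []

    def test_gzip_detected_by_magic_bytes(self, tmp_path):
        path = tmp_path / "reads.fq"  # no .gz suffix on purpose
        with gzip.open(path, "wt") as fh:
            fh.write("@r1\nACGT\n+\nIIII\n")
        (read,) = read_fastq(path)
        assert read.bases == "ACGT"

    def test_length_mismatch_names_record_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nIII\n")
        with pytest.raises(ParseError, match="record 2"):
            list(read_fastq(path))

    def test_lowercase_upcased_and_bad_bases_rejected(self, tmp_path):
        path = tmp_path / "mixed.fastq"
        path.write_text("@r1\nacgtn\n+\nIIIII\n")
        (read,) = read_fastq(path)
        assert read.bases == "ACGTN"
        path.write_text("@r1\nACRT\n+\nIIII\n")
        with pytest.raises(ParseError):
            list(read_fastq(path))

    def test_roundtrip_preserves_everything(self, tmp_path, rng):
        reads = [
            LongRead(f"r{i}", "ACGTN"[: i + 1] * 3, tuple(int(q) for q in rng.integers(0, 51, (i + 1) * 3)))
            for i in range(5)
        ]
        out = tmp_path / "rt.fastq"
        write_fastq(reads, out)
        assert list(read_fastq(out)) == reads


class TestFasta:
    def test_multiline_concatenation_and_id_token(self, fasta_file):
        contigs = list(read_fasta(fasta_file))
        assert contigs[0] == Contig("c1", "ACGTACGT")
        assert [c.contig_id for c in contigs] == ["c1", "c2"]

    def test_duplicate_id_and_empty_sequence_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(ParseError, match="duplicate"):
            list(read_fasta(path))
        path.write_text(">c1\n")
        with pytest.raises(ParseError):
            list(read_fasta(path))

    def test_roundtrip(self, tmp_path):
        contigs = [Contig("a", "ACGT" * 50), Contig("b", "N" * 7)]
        out = tmp_path / "rt.fasta"
        write_fasta(contigs, out, width=13)
        assert list(read_fasta(out)) == contigs


class TestCigar:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("10S80M10S", (("S", 10), ("M", 80), ("S", 10))),
            ("*", ()),
            ("5H10S85M", (("H", 5), ("S", 10), ("M", 85))),
            ("3=1X2D4N1I2M", (("=", 3), ("X", 1), ("D", 2), ("N", 4), ("I", 1), ("M", 2))),
        ],
    )
    def test_parse_examples(self, text, expected):
        assert parse_cigar(text) == expected

    @pytest.mark.parametrize("bad", ["5M3S2M", "10Z", "0M5S", "M5", "5", "", "5S3H5M"])
    def test_invalid_cigars_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_cigar(bad)

    @given(
        st.lists(
            st.tuples(st.sampled_from("MID=XNP"), st.integers(1, 500)),
            min_size=1,
            max_size=10,
        ),
        st.integers(0, 20),
        st.integers(0, 20),
    )
    def test_parse_serialize_identity(self, core, s_left, s_right):
        ops = []
        if s_left:
            ops.append(("S", s_left))
        ops.extend(core)
        if s_right:
            ops.append(("S", s_right))
        text = cigar_to_string(ops)
        assert parse_cigar(text) == tuple(ops)
        assert cigar_to_string(parse_cigar(text)) == text


class TestAlignmentRecord:
    def test_query_consumption_invariant_enforced(self):
        with pytest.raises(ValueError, match="consumes"):
            AlignmentRecord(
                query_id="q", is_mapped=True, target_id="t",
                cigar=(("S", 10), ("M", 80)), stored_query_length=100,
            )

    def test_full_query_length_adds_hard_clips_back(self):
        rec = AlignmentRecord(
            query_id="q", is_mapped=True, target_id="t",
            cigar=(("H", 5), ("M", 95)), stored_query_length=95,
        )
        assert rec.full_query_length == 100


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:ctg\tLN:1000\n"


class TestReadAlignments:
    def _write(self, tmp_path, body):
        path = tmp_path / "x.sam"
        path.write_text(SAM_HEADER + body)
        return path

    def test_flag4_is_unmapped(self, tmp_path):
        path = self._write(tmp_path, "q1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
        (rec,) = read_alignments(path, "sam")
        assert not rec.is_mapped

    def test_primary_mapped_record_with_clips(self, tmp_path):
        path = self._write(
            tmp_path, "q1\t0\tctg\t1\t60\t10S90M\t*\t0\t0\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
        )
        (rec,) = read_alignments(path, "sam")
        assert rec.is_mapped and rec.is_primary
        assert rec.stored_query_length == 100
        assert rec.target_start == 0  # SAM 1-based POS converted
        assert rec.cigar == (("S", 10), ("M", 90))

    def test_flag256_is_secondary(self, tmp_path):
        path = self._write(tmp_path, "q1\t256\tctg\t1\t60\t100M\t*\t0\t0\t*\t*\n")
        (rec,) = read_alignments(path, "sam")
        assert rec.is_secondary and not rec.is_primary

    def test_paf_with_cigar_synthesizes_terminal_clips(self, tmp_path):
        path = tmp_path / "x.paf"
        path.write_text(
            "q1\t100\t10\t95\t+\tctg\t1000\t5\t90\t85\t85\t60\ttp:A:P\tcg:Z:85M\n"
        )
        (rec,) = read_alignments(path, "paf")
        assert rec.cigar == (("S", 10), ("M", 85), ("S", 5))
        assert rec.stored_query_length == 100
        assert rec.target_start == 5

    def test_paf_without_cigar_is_flagged_unusable(self, tmp_path):
        path = tmp_path / "x.paf"
        path.write_text("q1\t100\t0\t100\t+\tctg\t1000\t0\t100\t100\t100\t60\n")
        (rec,) = read_alignments(path, "paf")
        assert rec.is_mapped and not rec.has_cigar
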