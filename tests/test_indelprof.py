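"""Global affine alignment, indel extraction and homopolymer classification."""

import numpy as np
import pytest
from Bio import Align

from ontqc.indelprof import (
    IndelEvent,
    PairwiseAlignment,
    extract_indels,
    global_align,
    indel_error_counts,
    is_homopolymeric,
)
from ontqc.synthdata import plant_indels, random_sequence


def linear_nw_score(a, b, match=1, mismatch=-2, gap=-2):
    """Brute-force oracle: plain NW without affine decomposition."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    return int(H[n, m])


def biopython_score(a, b, match=1, mismatch=-2, gap_open=-4, gap_extend=-2):
    """Independent affine oracle. Biopython charges open for the first gap
    base and extend for the rest, so a gap of length L under our model
    (open + L*extend) maps to open_gap_score = gap_open + gap_extend."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open + gap_extend
    al.extend_gap_score = gap_extend
    return al.score(a, b)


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 4
        assert aln.aligned_a == aln.aligned_b == "ACGT"

    def test_single_base_deletion_scores_minus_three(self):
        aln = global_align("ACGT", "AGT")
        assert aln.score == -3  # 3 matches + gap_open + gap_extend
        assert aln.aligned_a == "ACGT" and aln.aligned_b == "A-GT"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_round_trip_recovers_inputs(self, rng):
        for _ in range(20):
            a = random_sequence(int(rng.integers(1, 200)), rng)
            b = random_sequence(int(rng.integers(1, 200)), rng)
            aln = global_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b
            assert all(
                not (ca == "-" and cb == "-")
                for ca, cb in zip(aln.aligned_a, aln.aligned_b)
            )

    def test_linear_gap_scores_match_bruteforce_oracle(self, rng):
        for _ in range(200):
            a = random_sequence(int(rng.integers(1, 21)), rng)
            b = random_sequence(int(rng.integers(1, 21)), rng)
            got = global_align(a, b, gap_open=0, gap_extend=-2).score
            assert got == linear_nw_score(a, b)

    def test_affine_scores_match_biopython_oracle(self, rng):
        for _ in range(100):
            a = random_sequence(int(rng.integers(1, 60)), rng)
            b = random_sequence(int(rng.integers(1, 60)), rng)
            assert global_align(a, b).score == biopython_score(a, b)

    def test_score_invariant_under_joint_reversal(self, rng):
        for _ in range(20):
            a = random_sequence(int(rng.integers(1, 80)), rng)
            b = random_sequence(int(rng.integers(1, 80)), rng)
            assert global_align(a, b).score == global_align(a[::-1], b[::-1]).score

    def test_affine_prefers_one_long_gap_over_scattered_gaps(self):
        # deleting "GG" as one event: one gap of length 2, not two of 1
        aln = global_align("ACGGGTACGT", "ACGTACGT")
        events = extract_indels(aln)
        assert len(events) == 1 and len(events[0].seq) == 2


class TestExtractIndels:
    def test_single_insertion(self):
        aln = PairwiseAlignment("AC-GT", "ACTGT", 0)
        (ev,) = extract_indels(aln)
        assert ev == IndelEvent("insertion", 2, "T")

    def test_gapless_alignment_yields_nothing(self):
        assert extract_indels(PairwiseAlignment("ACGT", "ACGT", 4)) == []

    def test_multi_base_deletion_is_one_maximal_event(self):
        aln = PairwiseAlignment("ACGGGT", "AC--GT", 0)
        (ev,) = extract_indels(aln)
        assert ev.kind == "deletion" and ev.seq == "GG" and ev.ref_pos == 2

    def test_double_gap_column_rejected(self):
        with pytest.raises(ValueError):
            extract_indels(PairwiseAlignment("A-C", "A-C", 0))


class TestIsHomopolymeric:
    def test_deletion_inside_run(self):
        # CAAAG: deleting one A leaves run A x3 including the event base
        ev = IndelEvent("deletion", 2, "A")
        assert is_homopolymeric(ev, "CAAAG")

    def test_insertion_with_no_adjacent_run(self):
        ev = IndelEvent("insertion", 3, "G")  # between C and T in ..ACT..
        assert not is_homopolymeric(ev, "AACTAA")

    def test_multi_base_mixed_sequence_never_homopolymeric(self):
        assert not is_homopolymeric(IndelEvent("deletion", 0, "AG"), "AGAGAG")

    def test_insertion_extending_short_run_counts_event_bases(self):
        # inserting A next to AA makes a run of 3
        ev = IndelEvent("insertion", 2, "A")
        assert is_homopolymeric(ev, "CAAG" + "T" * 4)

    def test_min_run_is_tunable(self):
        ev = IndelEvent("deletion", 1, "A")
        assert is_homopolymeric(ev, "CAAG", min_run=2)
        assert not is_homopolymeric(ev, "CAAG", min_run=4)


class TestIndelErrorCounts:
    def test_identical_pairs_count_nothing(self, rng):
        seq = random_sequence(2_000, rng)
        counts = indel_error_counts([("g1", seq, seq)])
        assert (counts.n_homopolymeric, counts.n_random) == (0, 0)

    def test_planted_truth_recovered_exactly(self, rng):
        seq = random_sequence(5_000, rng)
        mutated, truth = plant_indels(seq, n_homo=3, n_random=2, seed=17)
        counts = indel_error_counts([("gene", seq, mutated)])
        assert (counts.n_homopolymeric, counts.n_random) == (3, 2)
        assert counts.n_total == len(truth.params["events"])

    def test_swapping_pair_order_preserves_class_counts(self, rng):
        seq = random_sequence(3_000, rng)
        mutated, _ = plant_indels(seq, n_homo=2, n_random=2, seed=5)
        fwd = indel_error_counts([("g", seq, mutated)])
        rev = indel_error_counts([("g", mutated, seq)])
        assert (fwd.n_homopolymeric, fwd.n_random) == (rev.n_homopolymeric, rev.n_random)

    def test_totals_sum_over_genes(self, rng):
        pairs = []
        expected = [(1, 1), (2, 0), (0, 2)]
        for i, (nh, nr) in enumerate(expected):
            seq = random_sequence(4_000, np.random.default_rng(50 + i))
            mutated, _ = plant_indels(seq, nh, nr, seed=60 + i)
            pairs.append((f"g{i}", seq, mutated))
        counts = indel_error_counts(pairs)
        assert [(h, r) for _, h, r in counts.per_gene] == expected
        assert counts.n_homopolymeric == 3 and counts.n_random == 3

    def test_empty_gene_named_in_error(self):
        with pytest.raises(ValueError, match="busco7"):
            indel_error_counts([("busco7", "", "ACGT")])
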