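"""Alignment, error/identity rates, polymer accuracy, chunk match rate."""

import edlib
import numpy as np
import pytest

from squeezecall.basecall_eval import (AlignmentReport, NoRunsError, align,
                                       chunk_match_rate, error_rates, find_runs,
                                       identity_rate, polymer_accuracy)
import squeezecall as sq


class TestAlign:
    def test_identical_sequences(self):
        report = align("ACGT", "ACGT")
        assert (report.matches, report.alignment_length) == (4, 4)
        assert report.ops == "MMMM"

    def test_single_mismatch(self):
        report = align("ACGT", "ACGG")
        assert (report.matches, report.mismatches) == (3, 1)

    def test_extra_read_base_is_insertion(self):
        # ops are relative to the reference: read base absent in ref = insertion
        report = align("ACGT", "ACT")
        assert report.insertions == 1 and report.deletions == 0
        assert report.read_length == 4 and report.ref_length == 3

    def test_missing_read_base_is_deletion(self):
        report = align("ACT", "ACGT")
        assert report.deletions == 1 and report.insertions == 0

    def test_count_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            read = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 25)))
            ref = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 25)))
            r = align(read, ref)
            assert r.alignment_length == r.matches + r.mismatches + \
                r.insertions + r.deletions
            assert r.read_length == len(read)
            assert r.ref_length == len(ref)
            assert len(r.ops) == r.alignment_length

    @pytest.mark.parametrize("seed", range(10))
    def test_edit_distance_matches_edlib(self, seed):
        # independent oracle: edlib's NW edit distance on random pairs
        rng = np.random.default_rng(seed)
        for _ in range(20):
            read = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 31)))
            ref = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 31)))
            mine = align(read, ref).edit_distance
            assert mine == edlib.align(read, ref, mode="NW")["editDistance"]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align("ACGT", "")

    def test_semiglobal_ignores_reference_flanks(self):
        report = align("ACGT", "TTTTACGTGGGG", mode="semiglobal")
        assert report.matches == 4 and report.edit_distance == 0


class TestErrorRates:
    def test_perfect_alignment_zero_rates(self):
        rates = error_rates(align("ACGT", "ACGT"))
        assert rates.error == 0.0

    def test_hand_counts(self):
        report = AlignmentReport(matches=6, mismatches=2, insertions=1,
                                 deletions=1, ops="MMMXXIDMMM")
        rates = error_rates(report)
        assert (rates.deletion, rates.insertion, rates.mismatch) == (0.1, 0.1, 0.2)
        assert rates.error == pytest.approx(0.4)

    def test_error_is_one_minus_match_fraction(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            read = "".join(rng.choice(list("ACGT"), size=15))
            ref = "".join(rng.choice(list("ACGT"), size=18))
            report = align(read, ref)
            assert error_rates(report).error == pytest.approx(
                1 - report.matches / report.alignment_length)


class TestIdentityRate:
    def test_perfect_read(self):
        assert identity_rate(align("ACGTACGT", "ACGTACGT")) == 1.0

    def test_hand_value(self):
        report = AlignmentReport(matches=9, mismatches=1, insertions=0,
                                 deletions=0, ops="MMMMMMMMMX")
        assert identity_rate(report) == pytest.approx(0.9)

    def test_identity_can_exceed_one_minus_error(self):
        # documented non-property: deletions inflate the alignment length
        # (error denominator) but not the read length (identity denominator)
        report = align("ACGT", "ACGTAAAAAAAA")
        assert identity_rate(report) == 1.0
        assert error_rates(report).error > 0.0


class TestPolymerAccuracy:
    def test_correct_homopolymer(self):
        assert polymer_accuracy([("AAACG", "AAACG")], "A", 3) == 1.0

    def test_short_call_scores_zero(self):
        assert polymer_accuracy([("AAA", "AAAA")], "A", 4) == 0.0

    def test_two_runs_one_correct(self):
        ref = "GGGTTAGGGA"   # two separate GGG runs
        read = "GGGTTAGGA"   # second run called one base short
        assert polymer_accuracy([(read, ref)], "G", 3) == 0.5

    def test_heteropolymer_tandem_repeat(self):
        assert polymer_accuracy([("TTACACACTT", "TTACACACTT")], "AC", 6) == 1.0
        assert polymer_accuracy([("TTACACTT", "TTACACACTT")], "AC", 6) == 0.0

    def test_run_finder_maximality(self):
        assert find_runs("AAAA", "A", 4) == [(0, 4)]
        assert find_runs("AAAA", "A", 3) == []          # run of 4 is not a run of 3
        assert find_runs("ACACA", "AC", 4) == [(0, 4)]  # partial period ignored
        assert find_runs("GACACG", "AC", 4) == [(1, 5)]

    def test_homopolymer_length_below_three_rejected(self):
        with pytest.raises(ValueError):
            polymer_accuracy([("AA", "AA")], "A", 2)

    def test_no_runs_signaled(self):
        with pytest.raises(NoRunsError):
            polymer_accuracy([("ACGT", "ACGT")], "A", 3)


class TestChunkMatchRate:
    def test_all_perfect(self):
        assert chunk_match_rate(["ACGT", "GGTA"], ["ACGT", "GGTA"]) == 1.0

    def test_median_of_three(self):
        # per-chunk rates 0.8, 0.9, 1.0 -> median 0.9
        calls = ["ACGTA", "ACGTACGTAC", "ACGT"]
        labels = ["ACGTT", "ACGTACGTAG", "ACGT"]
        assert chunk_match_rate(calls, labels) == pytest.approx(0.9)

    def test_even_count_averages_middle_two(self):
        calls = ["ACGTA", "ACGT"]          # rates 0.8 and 1.0
        labels = ["ACGTT", "ACGT"]
        assert chunk_match_rate(calls, labels) == pytest.approx(0.9)

    def test_single_chunk_is_its_own_median(self):
        assert chunk_match_rate(["ACGG"], ["ACGT"]) == pytest.approx(0.75)

    def test_duplicating_pairs_preserves_median(self):
        calls, labels = ["ACGTA", "ACGT", "AGGT"], ["ACGTT", "ACGT", "ACGT"]
        base = chunk_match_rate(calls, labels)
        assert chunk_match_rate(calls * 2, labels * 2) == pytest.approx(base)


def test_end_to_end_oracle_posteriors_recover_sequence(clean_pore_model):
    """A posteriorgram built from the exact alignment decodes to the truth.

    One-hot frames from the simulator's frame labels, with a blank at each
    dwell transition inside a repeated base, must beam-decode to the chunk
    label exactly — the whole decode chain is identity under a perfect model.
    """
    from squeezecall.chunking_io import chunk_read
    from squeezecall.encoder_model import frame_sample_centers
    from squeezecall.ctc_decode import beam_search

    read = sq.simulate_read(sq.random_sequence(60, seed=3), clean_pore_model, seed=4)
    chunk_len = len(read.signal) - len(read.signal) % 4
    chunk = chunk_read(read, chunk_len, mode="train")[0]
    centers = frame_sample_centers(sq.EncoderConfig.preset("tiny").conv_specs,
                                   chunk_len)
    idx = np.clip(np.rint(centers).astype(int), 0, chunk.valid_len - 1)
    base_ids = read.base_index[idx]
    classes = chunk.sample_classes[idx]
    post = np.full((len(centers), 5), 1e-6)
    prev_base = -1
    for f in range(len(centers)):
        cls = classes[f]
        if base_ids[f] != prev_base and f > 0 and classes[f - 1] == cls \
                and base_ids[f] != base_ids[f - 1]:
            post[f - 1] = 1e-6              # separate repeated bases by a blank
            post[f - 1, 4] = 1.0
        post[f, cls] = 1.0
        prev_base = base_ids[f]
    post = np.log(post / post.sum(axis=1, keepdims=True))
    seq, _ = beam_search(post, width=5)
    assert seq == chunk.label
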