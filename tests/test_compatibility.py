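"""Compatibility priors: end distances/filters, score decay, coverage weights."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrassign.compatibility import (
    PRESETS,
    CompatConfig,
    build_compatibility,
    coverage_profile,
    end_distances,
    end_filter_indicators,
    position_weights,
    psw_factor,
    score_decay,
)
from lrassign.transcriptome import TranscriptomeIndex

from conftest import make_record


class TestEndDistances:
    @pytest.mark.parametrize(
        "start,end,length,expected",
        [(10, 990, 1000, (10, 10)), (0, 500, 500, (0, 0)), (0, 1, 500, (0, 499))],
    )
    def test_hand_cases(self, start, end, length, expected):
        rec = make_record(start=start, end=end)
        assert end_distances(rec, length) == expected


class TestEndFilters:
    def test_disabled_filter_always_passes(self, toy_index):
        primary = make_record(start=20, end=990)
        far = make_record(transcript_id="t2", start=700, end=750, is_primary=False)
        config = CompatConfig()  # both betas -inf
        assert end_filter_indicators(far, primary, config, toy_index) == (1, 1)

    def test_tolerance_boundary(self, toy_index):
        # primary delta_s = 20; candidate delta_s = 820 is exactly 800 worse
        primary = make_record(start=20, end=990)
        config = PRESETS["ont-drna"]  # beta_s = -800, beta_e disabled
        at_limit = make_record(start=820, end=990, is_primary=False)
        beyond = make_record(start=821, end=990, is_primary=False)
        assert end_filter_indicators(at_limit, primary, config, toy_index)[0] == 1
        assert end_filter_indicators(beyond, primary, config, toy_index)[0] == 0

    def test_primary_against_itself_passes(self, toy_index):
        primary = make_record(start=500, end=900)
        config = CompatConfig(beta_s=-1.0, beta_e=-1.0)
        assert end_filter_indicators(primary, primary, config, toy_index) == (1, 1)


class TestScoreDecay:
    def test_zero_gap_gives_unit_sigma(self):
        recs = [
            make_record(transcript_id="t1", score=900),
            make_record(transcript_id="t2", score=900, is_primary=False),
        ]
        assert score_decay(recs) == {"t1": 1.0, "t2": 1.0}

    def test_hand_values(self):
        recs = [
            make_record(transcript_id="t1", score=900),
            make_record(transcript_id="t2", score=895, is_primary=False),
            make_record(transcript_id="t3", score=850, is_primary=False),
        ]
        sigma = score_decay(recs, lambda_decay=5.0)
        assert sigma["t1"] == 1.0
        assert sigma["t2"] == pytest.approx(math.exp(-1), rel=1e-12)
        assert sigma["t3"] == pytest.approx(math.exp(-10), rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        scores=st.lists(st.integers(0, 2000), min_size=1, max_size=6),
        shift=st.integers(-500, 500),
    )
    def test_translation_invariance(self, scores, shift):
        recs = [
            make_record(transcript_id=f"t{i}", score=float(s), is_primary=(i == 0))
            for i, s in enumerate(scores)
        ]
        shifted = [
            make_record(transcript_id=f"t{i}", score=float(s + shift), is_primary=(i == 0))
            for i, s in enumerate(scores)
        ]
        a, b = score_decay(recs), score_decay(shifted)
        for tid in a:
            assert a[tid] == pytest.approx(b[tid], abs=1e-12)

    def test_mixed_reads_rejected(self):
        recs = [make_record(read_id="r1"), make_record(read_id="r2")]
        with pytest.raises(ValueError, match="multiple reads"):
            score_decay(recs)


class TestCoverageProfile:
    def test_single_record_tally(self):
        index = TranscriptomeIndex({"t": 200})
        prof = coverage_profile([make_record(transcript_id="t", start=0, end=100)], index)
        counts = prof.base_counts("t")
        assert counts[:100].tolist() == [1] * 100 and counts[100:].sum() == 0
        assert prof.mean_coverage("t") == 0.5

    def test_uncovered_transcript_is_all_zero(self, toy_index):
        prof = coverage_profile([make_record(transcript_id="t1", end=100)], toy_index)
        assert prof.base_counts("t3").sum() == 0 and prof.mean_coverage("t3") == 0.0

    def test_stacked_full_length_records(self):
        index = TranscriptomeIndex({"t": 200})
        recs = [
            make_record(read_id=f"r{i}", transcript_id="t", start=0, end=200)
            for i in range(2)
        ]
        prof = coverage_profile(recs, index)
        assert np.all(prof.base_counts("t") == 2) and prof.mean_coverage("t") == 2.0

    def test_conservation_of_aligned_bases(self, toy_index, random_record_factory):
        from lrassign.alignment_io import dedupe_best_per_pair

        records = dedupe_best_per_pair(random_record_factory(3))
        prof = coverage_profile(records, toy_index)
        lhs = sum(
            toy_index.length(t) * prof.mean_coverage(t) for t in toy_index
        )
        assert lhs == pytest.approx(sum(r.span for r in records), abs=1e-9)
        # mean coverage is exactly the mean of the per-base tallies
        for t in prof.per_base:
            assert prof.mean_coverage(t) == pytest.approx(
                prof.base_counts(t).mean(), abs=1e-12
            )


class TestPositionWeights:
    def test_two_base_example(self):
        index = TranscriptomeIndex({"t": 2})
        prof = coverage_profile([make_record(transcript_id="t", start=0, end=1)], index)
        w = position_weights(prof, "t")
        assert w.tolist() == [0.0, 1.0]

    def test_uniform_coverage_is_degenerate(self):
        index = TranscriptomeIndex({"t": 100})
        prof = coverage_profile([make_record(transcript_id="t", start=0, end=100)], index)
        assert position_weights(prof, "t") is None

    def test_three_base_example(self):
        # c = [2, 1, 0] -> eta = [-1, 0, 1] -> shifted [0, 1, 2] -> [0, 1/3, 2/3]
        index = TranscriptomeIndex({"t": 3})
        recs = [
            make_record(read_id="a", transcript_id="t", start=0, end=2),
            make_record(read_id="b", transcript_id="t", start=0, end=1),
        ]
        w = position_weights(coverage_profile(recs, index), "t")
        assert w == pytest.approx([0.0, 1 / 3, 2 / 3], abs=1e-12)

    def test_weights_sum_to_one_when_defined(self, toy_index, random_record_factory):
        prof = coverage_profile(random_record_factory(11), toy_index)
        for t in toy_index:
            w = position_weights(prof, t)
            if w is not None:
                assert w.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(w >= 0)

    def test_sparse_bases_weigh_more_than_covered_bases(self):
        index = TranscriptomeIndex({"t": 4})
        recs = [
            make_record(read_id=f"r{i}", transcript_id="t", start=0, end=2)
            for i in range(3)
        ] + [make_record(read_id="r3", transcript_id="t", start=2, end=4)]
        w = position_weights(coverage_profile(recs, index), "t")
        assert w[2] > w[0] and w[3] > w[1]


class TestPswFactor:
    def test_full_span_alignment_sums_to_one(self):
        index = TranscriptomeIndex({"t": 3})
        recs = [
            make_record(read_id="a", transcript_id="t", start=0, end=2),
            make_record(read_id="b", transcript_id="t", start=0, end=1),
        ]
        w = position_weights(coverage_profile(recs, index), "t")
        assert psw_factor(make_record(transcript_id="t", start=0, end=3), w) == pytest.approx(1.0)

    def test_partial_intervals(self):
        index = TranscriptomeIndex({"t": 3})
        recs = [
            make_record(read_id="a", transcript_id="t", start=0, end=2),
            make_record(read_id="b", transcript_id="t", start=0, end=1),
        ]
        w = position_weights(coverage_profile(recs, index), "t")
        assert psw_factor(make_record(transcript_id="t", start=0, end=1), w) == 0.0
        assert psw_factor(make_record(transcript_id="t", start=1, end=3), w) == pytest.approx(1.0)


class TestBuildCompatibility:
    def test_single_alignment_row_is_one(self, toy_index):
        X = build_compatibility([make_record(end=900)], toy_index)
        assert X.row("r1") == {"t1": 1.0}

    def test_score_gap_row(self, toy_index):
        recs = [
            make_record(transcript_id="t1", score=900, end=900),
            make_record(transcript_id="t2", score=895, end=700, is_primary=False),
        ]
        X = build_compatibility(recs, toy_index)
        row = X.row("r1")
        assert row["t1"] == 1.0
        assert row["t2"] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_primary_entry_is_row_maximum_without_psw(self, toy_index, random_record_factory):
        from lrassign.alignment_io import dedupe_best_per_pair

        for seed in range(4):
            records = dedupe_best_per_pair(random_record_factory(seed))
            X = build_compatibility(records, toy_index)
            primary_of = {r.read_id: r.transcript_id for r in records if r.is_primary}
            for rid, tid in primary_of.items():
                row = X.row(rid)
                assert row[tid] == pytest.approx(max(row.values()), abs=1e-12)

    def test_psw_zero_row_falls_back_to_drop_model(self):
        # coverage c = [3, 3, 1, 1] gives weights [0, 0, .5, .5]; a read
        # aligned only over [0, 2) has zero psw mass and must fall back
        index = TranscriptomeIndex({"t": 4})
        recs = [
            make_record(read_id="a", transcript_id="t", start=0, end=2),
            make_record(read_id="b", transcript_id="t", start=0, end=2),
            make_record(read_id="c", transcript_id="t", start=0, end=4),
        ]
        X = build_compatibility(recs, index, CompatConfig(psw=True))
        assert X.row("a") == {"t": 1.0}  # fallback: f_eta reset to 1
        assert X.row("c") == {"t": 1.0}  # full span: f_eta = 1 already

    def test_end_filter_removes_far_secondary(self, toy_index):
        recs = [
            make_record(transcript_id="t1", score=900, start=10, end=990),
            make_record(transcript_id="t2", score=890, start=700, end=790, is_primary=False),
        ]
        X = build_compatibility(recs, toy_index, CompatConfig(beta_s=-100.0))
        assert set(X.row("r1")) == {"t1"}

    def test_every_row_has_positive_entry(self, toy_index, random_record_factory):
        from lrassign.alignment_io import dedupe_best_per_pair

        for psw in (False, True):
            records = dedupe_best_per_pair(random_record_factory(8, n_reads=25))
            X = build_compatibility(
                records, toy_index, CompatConfig(psw=psw, beta_s=-200.0)
            )
            row_counts = np.diff(X.X.indptr)
            assert np.all(row_counts >= 1)
            assert np.all(X.X.data > 0)


def test_lambda_must_be_positive():
    with pytest.raises(ValueError):
        CompatConfig(lambda_decay=0.0)
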