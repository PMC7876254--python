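"""Rate/count/fixation scores against brute-force oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

import gazediag as g
from conftest import make_recording
from gazediag.errors import ValidationError
from gazediag.scoring import aoi_count_score, aoi_rate_score, score_participant
from oracles import naive_count_score, naive_rate_score

CX, CY = 200.0, 200.0  # center of tiny_stimulus inner circle


def random_recording(rng, tiny_stimulus, n=None):
    clip = tiny_stimulus.clips[0]
    n = n if n is not None else clip.n_samples(50)
    xs = rng.uniform(0, 640, n)
    ys = rng.uniform(0, 512, n)
    valid = rng.random(n) > 0.2
    return make_recording("r", "clip1", xs, ys, valid)


class TestRateScore:
    def test_all_samples_inside_saturates_at_one(self, stimulus):
        clip = stimulus.clip("still")
        rec = make_recording("p", "still", [640.0] * 225, [420.0] * 225)
        aoi = stimulus.aoi("still.face")
        assert aoi_rate_score(rec, clip, aoi, "full") == 1.0

    def test_partial_dwell_fraction(self, stimulus):
        # 45 of 225 samples inside: 45 * 20 ms / 4500 ms = 0.2
        clip = stimulus.clip("still")
        xs = [640.0] * 45 + [10.0] * 180
        rec = make_recording("p", "still", xs, [420.0] * 225)
        assert aoi_rate_score(rec, clip, stimulus.aoi("still.face"), "full") == pytest.approx(0.2)

    def test_first_second_window_full_dwell(self, stimulus):
        clip = stimulus.clip("still")
        xs = [640.0] * 50 + [10.0] * 175
        rec = make_recording("p", "still", xs, [420.0] * 225)
        assert aoi_rate_score(rec, clip, stimulus.aoi("still.face"), "first_1s") == 1.0

    def test_invalid_samples_never_count_inside(self, stimulus):
        clip = stimulus.clip("still")
        rec = make_recording("p", "still", [640.0] * 225, [420.0] * 225, valid=[False] * 225)
        assert aoi_rate_score(rec, clip, stimulus.aoi("still.face"), "full") == 0.0

    def test_window_longer_than_clip_is_error(self, tiny_stimulus):
        clip = tiny_stimulus.clips[0]
        rec = make_recording("p", "clip1", [CX] * 50, [CY] * 50)
        with pytest.raises(ValidationError, match="window"):
            aoi_rate_score(rec, clip, tiny_stimulus.aoi("clip1.inner"), "first_2s")


class TestCountScore:
    def test_single_inside_sample_counts(self, tiny_stimulus):
        clip = tiny_stimulus.clips[0]
        xs = [10.0] * 20 + [CX] + [10.0] * 29
        rec = make_recording("p", "clip1", xs, [CY] * 50)
        assert aoi_count_score(rec, clip, tiny_stimulus.aoi("clip1.inner")) == 1

    def test_no_inside_samples_gives_zero(self, tiny_stimulus):
        clip = tiny_stimulus.clips[0]
        rec = make_recording("p", "clip1", [10.0] * 50, [10.0] * 50)
        assert aoi_count_score(rec, clip, tiny_stimulus.aoi("clip1.inner")) == 0

    def test_min_run_requires_consecutive_dwell(self, tiny_stimulus):
        # runs of length 3 only -> no run of 5
        clip = tiny_stimulus.clips[0]
        xs = ([CX] * 3 + [10.0] * 2) * 10
        rec = make_recording("p", "clip1", xs, [CY] * 50)
        aoi = tiny_stimulus.aoi("clip1.inner")
        assert aoi_count_score(rec, clip, aoi, min_run=5) == 0
        assert aoi_count_score(rec, clip, aoi, min_run=3) == 1


class TestFixationPercentage:
    def test_all_valid_is_hundred(self, stimulus):
        rec = g.GazeRecordingSet("p")
        for clip in stimulus.clips:
            n = clip.n_samples(50)
            rec.clips[clip.clip_id] = make_recording("p", clip.clip_id,
                                                     [5.0] * n, [5.0] * n).clips[clip.clip_id]
        assert g.overall_fixation_percentage(rec, stimulus) == 100.0

    def test_half_valid_is_fifty(self, stimulus):
        rec = g.GazeRecordingSet("p")
        for clip in stimulus.clips:
            n = clip.n_samples(50)
            valid = [i % 2 == 0 for i in range(n)]
            rec.clips[clip.clip_id] = make_recording(
                "p", clip.clip_id, [5.0] * n, [5.0] * n, valid).clips[clip.clip_id]
        assert g.overall_fixation_percentage(rec, stimulus) == pytest.approx(50.0, abs=0.3)

    def test_missing_clip_listed_in_error(self, stimulus):
        rec = make_recording("p", "still", [5.0] * 225, [5.0] * 225)
        with pytest.raises(ValidationError, match="drawing"):
            g.overall_fixation_percentage(rec, stimulus)


class TestOracleEquivalence:
    def test_scores_match_naive_loop_on_random_recordings(self, tiny_stimulus):
        rng = np.random.default_rng(42)
        clip = tiny_stimulus.clips[0]
        for _ in range(60):
            rec = random_recording(rng, tiny_stimulus)
            df = rec.samples("clip1")
            samples = list(zip(df.t_ms, df.x_px, df.y_px, df.valid))
            for aoi_id in ("clip1.inner", "clip1.outer"):
                aoi = tiny_stimulus.aoi(aoi_id)
                for window, w_ms in (("full", None), ("first_1s", 1000.0)):
                    assert aoi_rate_score(rec, clip, aoi, window) == pytest.approx(
                        naive_rate_score(samples, aoi, w_ms, 1000.0)
                    )
                for mr in (1, 3):
                    assert aoi_count_score(rec, clip, aoi, mr) == naive_count_score(
                        samples, aoi, mr
                    )


class TestScoringInvariants:
    def test_containment_monotonicity(self, tiny_stimulus):
        # inner circle lies within outer rect: rate(inner) <= rate(outer)
        rng = np.random.default_rng(7)
        clip = tiny_stimulus.clips[0]
        inner = tiny_stimulus.aoi("clip1.inner")
        outer = tiny_stimulus.aoi("clip1.outer")
        for _ in range(25):
            rec = random_recording(rng, tiny_stimulus)
            for w in ("full", "first_1s"):
                assert aoi_rate_score(rec, clip, inner, w) <= aoi_rate_score(rec, clip, outer, w)

    def test_truncation_after_2s_preserves_prefix_rates(self, stimulus):
        rng = np.random.default_rng(3)
        clip = stimulus.clip("still")
        n = clip.n_samples(50)
        xs, ys = rng.uniform(0, 1280, n), rng.uniform(0, 1024, n)
        full = make_recording("p", "still", xs, ys)
        cut = make_recording("p", "still", xs[:100], ys[:100])
        aoi = stimulus.aoi("still.face")
        for w in ("first_1s", "first_2s"):
            assert aoi_rate_score(full, clip, aoi, w) == aoi_rate_score(cut, clip, aoi, w)

    def test_count_is_one_whenever_rate_positive(self, tiny_stimulus):
        rng = np.random.default_rng(5)
        clip = tiny_stimulus.clips[0]
        aoi = tiny_stimulus.aoi("clip1.inner")
        for _ in range(25):
            rec = random_recording(rng, tiny_stimulus)
            rate = aoi_rate_score(rec, clip, aoi, "full")
            count = aoi_count_score(rec, clip, aoi, 1)
            assert (count == 1) == (rate > 0)


class TestAttributeMatrix:
    def test_shape_and_column_order(self, small_cohort, stimulus):
        _, matrix = small_cohort
        assert matrix.values.shape == (40, 400)
        expected = [s.attribute_id for s in g.enumerate_attribute_space(stimulus)]
        assert list(matrix.values.columns) == expected

    def test_matrix_rows_match_per_participant_scoring(self, small_cohort, stimulus):
        cohort, matrix = small_cohort
        pid = cohort.participants[0].participant_id
        row, fix = score_participant(cohort.recordings[pid], stimulus)
        assert np.allclose(matrix.values.loc[pid].to_numpy(), row)
        assert matrix.fixation_pct.loc[pid] == pytest.approx(fix)

    def test_all_invalid_participant_scores_zero(self, stimulus):
        rec = g.GazeRecordingSet("z")
        for clip in stimulus.clips:
            n = clip.n_samples(50)
            rec.clips[clip.clip_id] = make_recording(
                "z", clip.clip_id, [np.nan] * n, [np.nan] * n, [False] * n
            ).clips[clip.clip_id]
        matrix = g.build_attribute_matrix({"z": rec}, stimulus)
        assert (matrix.values.loc["z"] == 0).all()
        assert matrix.fixation_pct.loc["z"] == 0.0

    def test_row_order_independent_of_input_order(self, small_cohort, stimulus):
        cohort, matrix = small_cohort
        subset = {k: cohort.recordings[k] for k in list(cohort.recordings)[:6]}
        reversed_subset = dict(reversed(list(subset.items())))
        m1 = g.build_attribute_matrix(subset, stimulus)
        m2 = g.build_attribute_matrix(reversed_subset, stimulus)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_csv_round_trip(self, small_cohort, stimulus, tmp_path):
        _, matrix = small_cohort
        path = tmp_path / "matrix.csv"
        matrix.to_csv(path)
        again = g.AttributeMatrix.from_csv(path, stimulus)
        pd.testing.assert_frame_equal(matrix.values, again.values)
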