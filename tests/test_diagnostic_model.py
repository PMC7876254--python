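"""Sub-algorithms, sigmoid fits, age merging and the best-fit hierarchy."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import gazediag as g
from gazediag.attribute_selection import SelectedCandidate
from gazediag.diagnostic_model import (
    _age_weight,
    _bce,
    _sigmoid,
    save_model,
)
from gazediag.errors import FitError


def cand(attr_id, kind, orientation):
    aoi = attr_id.split(":")[0]
    return SelectedCandidate(attribute_id=attr_id, aoi_id=aoi, kind=kind,
                             orientation=orientation, d=1.0, p=0.01)


class TestAggregateAttributes:
    def test_negative_orientation_flips_count(self):
        c = [cand("a:count", "count", -1)]
        assert g.aggregate_attributes(c, {"a:count": 0.0}, {}) == 1.0

    def test_mean_over_count_candidates(self):
        cs = [cand("a:count", "count", 1), cand("b:count", "count", 1)]
        row = {"a:count": 1.0, "b:count": 0.0}
        assert g.aggregate_attributes(cs, row, {}) == 0.5

    def test_rate_standardization_identity(self):
        c = [cand("a:rate_full", "rate_full", 1)]
        assert g.aggregate_attributes(c, {"a:rate_full": 0.07}, {"a:rate_full": 0.07}) == 1.0

    def test_zero_sd_rate_contributes_nothing(self):
        c = [cand("a:rate_full", "rate_full", 1)]
        assert g.aggregate_attributes(c, {"a:rate_full": 0.5}, {"a:rate_full": 0.0}) == 0.0


class TestFitSigmoid:
    def test_separated_classes_cross_half(self):
        x = np.r_[np.full(10, 2.0) + np.linspace(0, 0.5, 10), np.full(10, -1.0)]
        y = np.r_[np.ones(10), np.zeros(10)]
        a, b = g.fit_sigmoid(x, y)
        s = _sigmoid(a * x + b)
        assert (s[:10] > 0.5).all() and (s[10:] < 0.5).all()

    def test_permuted_labels_give_flat_fit_matching_logistic_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = rng.permutation(np.r_[np.ones(80), np.zeros(120)])
        a, b = g.fit_sigmoid(x, y)
        s = _sigmoid(a * x + b)
        # sklearn logistic regression on the same data as independent oracle
        lr = LogisticRegression(C=1e6, tol=1e-10).fit(x[:, None], y)
        oracle = lr.predict_proba(x[:, None])[:, 1]
        assert a == pytest.approx(max(lr.coef_[0][0], 0.0), abs=0.05)
        assert np.allclose(s, oracle, atol=0.02)
        assert s.mean() == pytest.approx(y.mean(), abs=0.03)

    def test_fit_never_worse_than_null_model(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=40)
            y = (rng.random(40) < 0.4).astype(float)
            if y.min() == y.max():
                continue
            a, b = g.fit_sigmoid(x, y)
            fitted = _bce(_sigmoid(a * x + b), y)
            prev = y.mean()
            null = _bce(np.full_like(y, prev), y)
            assert fitted <= null + 1e-9

    def test_slope_constrained_non_negative(self):
        # anti-oriented data: optimum would want a < 0, constraint clips to 0
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.ones(10), np.zeros(10)]
        a, _ = g.fit_sigmoid(x, y)
        assert a >= 0.0

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            g.fit_sigmoid([1.0, 2.0], [1, 1])


@pytest.fixture(scope="module")
def fitted(small_cohort):
    cohort, matrix = small_cohort
    cfg = g.FitConfig(seed=5)
    young = g.fit_sub_algorithm(matrix, cohort.participants, "younger", "rate", cfg)
    old = g.fit_sub_algorithm(matrix, cohort.participants, "older", "rate", cfg)
    merged = g.merge_bands(young, old, cohort.participants, matrix, cfg)
    return cohort, matrix, young, old, merged


@pytest.fixture(scope="module")
def model(small_cohort):
    cohort, matrix = small_cohort
    return g.fit_best_fit(cohort.participants, matrix, g.FitConfig(seed=5))


class TestMergedAlgorithm:
    def test_age_weight_limits(self):
        ages = np.array([5.0, 17.0])
        w = _age_weight(ages, k=50.0, a0=10.0)
        assert w[0] == pytest.approx(1.0, abs=1e-6)
        assert w[1] == pytest.approx(0.0, abs=1e-6)

    def test_scores_strictly_inside_unit_interval(self, fitted):
        cohort, matrix, _, _, merged = fitted
        ages = np.array([p.age_years for p in cohort.participants])
        s = merged.score(matrix.values, ages)
        assert ((s > 0) & (s < 1)).all()

    def test_age_continuity(self, fitted):
        cohort, matrix, _, _, merged = fitted
        row = matrix.values.iloc[[0]]
        base = merged.score(row, np.array([9.999]))[0]
        close = merged.score(row, np.array([10.001]))[0]
        assert abs(base - close) < 0.01

    def test_merged_auc_not_worse_than_hard_band_split_oracle(self, fitted):
        cohort, matrix, young, old, merged = fitted
        labelled = [p for p in cohort.participants if p.asd_label is not None]
        ids = [p.participant_id for p in labelled]
        ages = np.array([p.age_years for p in labelled])
        y = np.array([p.asd_label for p in labelled], dtype=bool)
        values = matrix.values.loc[ids]
        s_merged = merged.score(values, ages)
        # oracle: hard switch at age 10 between the two sub-algorithm scores
        s_hard = np.where(ages < 10.0, young.score(values), old.score(values))
        assert g.auc(s_merged, y) >= g.auc(s_hard, y) - 0.02


class TestBestFit:
    def test_four_cells_and_modality_choices(self, model):
        for sub, band, fam in [
            (model.rate_final.young, "younger", "rate"),
            (model.rate_final.old, "older", "rate"),
            (model.count_final.young, "younger", "count"),
            (model.count_final.old, "older", "count"),
        ]:
            assert (sub.band, sub.family) == (band, fam)
            assert len(sub.candidates) > 0
        assert set(model.modality) == {"younger", "older"}
        assert set(model.modality.values()) <= {"rate", "count"}

    def test_decision_threshold_is_inclusive_at_half(self, model):
        assert model.labels(np.array([0.5]))[0]
        assert not model.labels(np.array([0.499999]))[0]

    def test_refit_is_bit_identical(self, small_cohort, tmp_path, model):
        cohort, matrix = small_cohort
        again = g.fit_best_fit(cohort.participants, matrix, g.FitConfig(seed=5))
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(model, p1)
        save_model(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_serialization_round_trip_preserves_scores(self, small_cohort, tmp_path, model):
        cohort, matrix = small_cohort
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = g.load_model(path)
        ids = [p.participant_id for p in cohort.participants]
        ages = [p.age_years for p in cohort.participants]
        np.testing.assert_allclose(
            model.score_rows(matrix.values.loc[ids], ages),
            loaded.score_rows(matrix.values.loc[ids], ages),
        )

    def test_monotone_in_asd_oriented_attribute(self, small_cohort, model):
        cohort, matrix = small_cohort
        fam = model.modality["younger"]
        merged = {"rate": model.rate_final, "count": model.count_final}[fam]
        c = merged.young.candidates.candidates[0]
        row = matrix.values.iloc[[0]].copy()
        lo = model.score_rows(row, [7.0])[0]
        bumped = row.copy()
        bumped[c.attribute_id] += 0.1 * c.orientation
        hi = model.score_rows(bumped, [7.0])[0]
        assert hi >= lo - 1e-12

    def test_empty_cell_error_names_cell(self, small_cohort):
        cohort, matrix = small_cohort
        strict = g.FitConfig(
            selection=g.SelectionConfig(p_threshold=1e-12, d_threshold=50.0)
        )
        with pytest.raises(FitError, match="band="):
            g.fit_best_fit(cohort.participants, matrix, strict)

    def test_empty_cells_allowed_give_constant_subalgorithm(self, small_cohort):
        cohort, matrix = small_cohort
        permissive = g.FitConfig(
            selection=g.SelectionConfig(p_threshold=1e-12, d_threshold=50.0),
            allow_empty_cells=True,
        )
        model = g.fit_best_fit(cohort.participants, matrix, permissive)
        s = model.rate_final.young.score(matrix.values)
        assert np.allclose(s, 0.5)


class TestPredict:
    def test_predict_from_raw_gaze_matches_matrix_route(self, small_cohort, stimulus):
        cohort, matrix = small_cohort
        model = g.fit_best_fit(cohort.participants, matrix, g.FitConfig(seed=5))
        p = cohort.participants[0]
        direct = g.predict(model, p, cohort.recordings[p.participant_id], stimulus)
        batch = g.predict_rows(model, [p], matrix)[0]
        assert direct.score == pytest.approx(batch.score)
        assert 0.0 < direct.score < 1.0
        assert direct.asd_predicted == (direct.score >= 0.5)

    def test_low_fixation_recording_is_flagged(self, small_cohort, stimulus):
        cohort, matrix = small_cohort
        model = g.fit_best_fit(cohort.participants, matrix, g.FitConfig(seed=5))
        cfg = g.SimConfig(seed=99)
        rec = g.simulate_degraded(stimulus, cfg, "deg1", age=8.0)
        assert g.overall_fixation_percentage(rec, stimulus) < 70.0
        part = g.Participant("deg1", 8.0, "unknown", None)
        pred = g.predict(model, part, rec, stimulus)
        assert pred.low_fixation
        assert 0.0 < pred.score < 1.0
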