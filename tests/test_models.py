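"""LASSO fitting, generic leave-one-out models, participant calibration."""

import numpy as np
import pytest

from tibload.config import RunConfig
from tibload.datatypes import SOURCE_GENERIC, LoadStimulusSeries
from tibload.errors import ValidationError
from tibload.models import (
    CALIBRATION_FEATURES,
    TRACKER_FEATURES,
    LinearModel,
    evaluate_quarter_calibration,
    fit_calibration,
    fit_generic,
    fit_lasso,
    predict_calibration,
    predict_generic,
)


class TestFitLasso:
    def test_zero_penalty_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        model = fit_lasso(X, y, lambda_grid=[0.0], seed=0)
        # closed-form OLS with intercept on the raw scale
        A = np.column_stack([np.ones(5), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        raw_coef = model.coef / model.scales
        np.testing.assert_allclose(raw_coef, beta[1:], atol=1e-6)
        np.testing.assert_allclose(model.predict(X), A @ beta, atol=1e-6)

    def test_noiseless_single_feature_recovery(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = 3.0 * X[:, 0]
        model = fit_lasso(X, y, seed=1)
        raw_coef = model.coef / model.scales
        assert raw_coef[0] == pytest.approx(3.0, abs=1e-6)
        np.testing.assert_allclose(raw_coef[1:], 0.0, atol=1e-6)
        resid = model.predict(X) - y
        assert float(np.max(np.abs(resid))) < 1e-8

    def test_constant_features_give_intercept_only(self):
        X = np.ones((10, 3))
        y = np.arange(10.0)
        model = fit_lasso(X, y, seed=0)
        np.testing.assert_allclose(model.coef, 0.0, atol=1e-12)
        assert model.predict(X)[0] == pytest.approx(y.mean())

    def test_fewer_rows_than_folds_warns(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="folds"):
            fit_lasso(X, y, seed=0, n_folds=5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            fit_lasso(np.empty((0, 2)), np.empty(0))

    def test_missing_values_rejected(self):
        X = np.array([[1.0], [np.nan], [2.0]])
        with pytest.raises(ValidationError):
            fit_lasso(X, np.zeros(3))

    def test_refit_is_bit_identical(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        y = X @ np.array([1.0, -2.0, 0.0, 0.5]) + rng.normal(0, 0.5, 50)
        m1 = fit_lasso(X, y, seed=42)
        m2 = fit_lasso(X.copy(), y.copy(), seed=42)
        assert m1.penalty == m2.penalty
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.intercept == m2.intercept

    def test_text_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = fit_lasso(X, y, feature_names=("a", "b", "c"), seed=0)
        back = LinearModel.from_text(model.to_text())
        assert back.feature_names == model.feature_names
        np.testing.assert_array_equal(back.coef, model.coef)
        np.testing.assert_array_equal(back.means, model.means)
        assert back.intercept == model.intercept
        assert back.penalty == model.penalty


class TestGenericModels:
    def test_one_model_per_held_out_participant(self, small_config, small_cohort, small_model_set):
        assert set(small_model_set.models) == {d.participant_id for d in small_cohort}

    def test_training_excludes_held_out_participant(
        self, small_config, small_cohort, small_insole_ls, small_model_set
    ):
        """The stored standardization means must equal the pooled feature means
        of the *other* participants — a leakage-sensitive statistic."""
        feats = {
            d.participant_id: d.tracker.feature_matrix(
                small_insole_ls[d.participant_id].minute_start
            )
            for d in small_cohort
        }
        for held_out, model in small_model_set.models.items():
            pooled = np.vstack([feats[p] for p in feats if p != held_out])
            np.testing.assert_allclose(model.means, pooled.mean(axis=0), rtol=1e-12)
            with_leak = np.vstack(list(feats.values())).mean(axis=0)
            assert not np.allclose(model.means, with_leak)

    def test_identical_participants_give_identical_models(
        self, noise_free_config, noise_free_cohort
    ):
        model_set = fit_generic(noise_free_cohort, config=noise_free_config, seed=3)
        models = list(model_set.models.values())
        np.testing.assert_allclose(models[0].coef, models[1].coef, atol=1e-9)
        assert models[0].intercept == pytest.approx(models[1].intercept, abs=1e-9)

    def test_single_participant_rejected(self, small_config, small_cohort):
        with pytest.raises(ValidationError):
            fit_generic(small_cohort[:1], config=small_config)

    def test_prediction_arithmetic_on_one_row(self):
        model = LinearModel(
            feature_names=TRACKER_FEATURES,
            coef=np.array([2.0, 0.0, -1.0, 0.5, 0.0]),
            intercept=10.0,
            means=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            scales=np.array([1.0, 2.0, 1.0, 2.0, 1.0]),
            penalty=0.1,
            seed=0,
        )
        x = np.array([2.0, 2.0, 5.0, 8.0, 5.0])
        expected = 10.0 + 2.0 * 1.0 + 0.0 - 1.0 * 2.0 + 0.5 * 2.0 + 0.0
        assert model.predict(x)[0] == pytest.approx(expected, rel=1e-12)

    def test_predictions_clamped_and_tagged(self, small_cohort, small_model_set):
        day = small_cohort[0]
        pred = predict_generic(small_model_set, day)
        assert np.all(pred.ls >= 0)
        assert set(pred.source) == {SOURCE_GENERIC}
        assert len(pred) == len(day.minute_starts)

    def test_unknown_participant_rejected(self, small_cohort, small_model_set):
        import dataclasses

        from tibload.datatypes import ParticipantDay

        day = small_cohort[0]
        stranger = ParticipantDay(
            meta=dataclasses.replace(day.meta, participant_id="P99"),
            insole=day.insole,
            tracker=day.tracker,
        )
        with pytest.raises(ValidationError):
            predict_generic(small_model_set, stranger)

    def test_prediction_invariant_to_minute_subsets(self, small_cohort, small_model_set):
        day = small_cohort[0]
        full = predict_generic(small_model_set, day)
        sub = predict_generic(small_model_set, day, minute_starts=day.minute_starts[10:20])
        np.testing.assert_array_equal(sub.ls, full.ls[10:20])


class TestCalibration:
    def test_window_restricted_to_covered_minutes(
        self, small_config, small_cohort, small_insole_ls, small_model_set
    ):
        day = small_cohort[0]
        ls = small_insole_ls[day.participant_id]
        gen = predict_generic(small_model_set, day)
        window = ls.minute_start[:60]
        cal = fit_calibration(day, gen, window, config=small_config, seed=11, insole_ls=ls)
        assert set(cal.window_minutes).issubset(set(window))
        assert cal.model.feature_names == CALIBRATION_FEATURES

    def test_too_few_usable_minutes_rejected(
        self, small_config, small_cohort, small_insole_ls, small_model_set
    ):
        day = small_cohort[0]
        ls = small_insole_ls[day.participant_id]
        gen = predict_generic(small_model_set, day)
        with pytest.raises(ValidationError):
            fit_calibration(day, gen, ls.minute_start[:1], config=small_config, insole_ls=ls)

    def test_low_information_window_flagged(
        self, small_config, small_cohort, small_insole_ls, small_model_set
    ):
        day = small_cohort[0]
        ls = small_insole_ls[day.participant_id]
        gen = predict_generic(small_model_set, day)
        # pick a window of unloaded (sedentary) minutes
        zero_minutes = ls.minute_start[ls.ls == 0.0][:15]
        assert len(zero_minutes) >= 10, "fixture day lacks a sedentary stretch"
        cal = fit_calibration(day, gen, zero_minutes, config=small_config, insole_ls=ls)
        assert cal.low_information_flag

    def test_perfect_first_stage_gives_near_zero_error(
        self, noise_free_config, noise_free_cohort
    ):
        day = noise_free_cohort[0]
        model_set = fit_generic(noise_free_cohort, config=noise_free_config, seed=3)
        from tibload.biomech import day_insole_ls

        ls = day_insole_ls(day, noise_free_config)
        gen = predict_generic(model_set, day)
        window = ls.minute_start[:120]
        cal = fit_calibration(day, gen, window, config=noise_free_config, seed=3, insole_ls=ls)
        held_out = ls.minute_start[120:]
        pred = predict_calibration(cal, day, gen, held_out)
        np.testing.assert_allclose(pred.ls, ls.subset(held_out).ls, atol=1e-6)

    def test_quarter_evaluation_requires_enough_coverage(
        self, small_config, small_cohort, small_model_set
    ):
        day = small_cohort[0]
        with pytest.raises(ValidationError):
            evaluate_quarter_calibration(
                day, small_model_set, config=small_config, min_minutes=10**6
            )

    def test_quarter_evaluation_deterministic(
        self, small_config, small_cohort, small_insole_ls, small_model_set
    ):
        day = small_cohort[0]
        ls = small_insole_ls[day.participant_id]
        gen = predict_generic(small_model_set, day)
        r1 = evaluate_quarter_calibration(
            day, small_model_set, config=small_config, seed=11, insole_ls=ls, generic_ls=gen
        )
        r2 = evaluate_quarter_calibration(
            day, small_model_set, config=small_config, seed=11, insole_ls=ls, generic_ls=gen
        )
        assert r1 == r2
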