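"""Image-level splitting, SVM grid search and evaluation arithmetic."""

import numpy as np
import pandas as pd
import pytest

from seedhsi.classify import (
    evaluate,
    grid_search_svm,
    load_model,
    predict_objects,
    report_from_confusion,
    save_model,
    split_by_image,
)


class TestSplitByImage:
    def test_per_class_55_images_split_36_18_1(self):
        """55 images per class: 1 external, remaining 54 at 2:1 -> 36/18."""
        ids = [f"v{c}_{i}" for c in (1, 2, 3) for i in range(55)]
        classes = [c for c in (1, 2, 3) for _ in range(55)]
        plan = split_by_image(ids, classes, ratio=(2, 1), n_external=1, rng_seed=4)
        assert len(plan.calibration_ids) == 3 * 36
        assert len(plan.prediction_ids) == 3 * 18
        assert len(plan.external_ids) == 3

    def test_three_images_split_two_one(self):
        plan = split_by_image(["a", "b", "c"], ratio=(2, 1), n_external=0, rng_seed=0)
        assert len(plan.calibration_ids) == 2
        assert len(plan.prediction_ids) == 1
        assert plan.external_ids == []

    def test_seeded_split_reproducible(self):
        ids = list(range(12))
        a = split_by_image(ids, rng_seed=7)
        b = split_by_image(ids, rng_seed=7)
        assert a.calibration_ids == b.calibration_ids
        assert a.prediction_ids == b.prediction_ids
        assert a.external_ids == b.external_ids

    def test_pools_are_disjoint_and_cover(self):
        ids = list(range(10))
        plan = split_by_image(ids, rng_seed=1)
        pooled = plan.calibration_ids + plan.prediction_ids + plan.external_ids
        assert sorted(pooled) == ids

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            split_by_image([1, 2, 3], n_external=1)


class TestGridSearch:
    def _blobs(self, rng, separation=6.0, n=30):
        X = np.vstack(
            [rng.normal(0, 1, (n, 2)), rng.normal(separation, 1, (n, 2))]
        )
        y = np.array([1] * n + [2] * n)
        return X, y

    def test_separable_blobs_reach_perfect_calibration(self, rng):
        X, y = self._blobs(rng)
        model = grid_search_svm(X, y, rng_seed=0)
        report = evaluate(model, X, y)
        assert report.overall_accuracy == 1.0
        # record covers the full default grid
        assert len(model.grid_record) == 17 * 17

    def test_xor_pattern_solved_by_rbf(self, rng):
        centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]])
        labels = np.array([1, 1, 2, 2])
        X = np.vstack([rng.normal(c, 0.3, (15, 2)) for c in centers])
        y = np.repeat(labels, 15)
        model = grid_search_svm(X, y, c_exponents=range(-2, 7), g_exponents=range(-4, 3), rng_seed=0)
        assert model.grid_record["cv_accuracy"].max() > 0.9

    def test_information_free_data_hits_majority_fraction(self):
        X = np.tile([0.5, 0.5], (30, 1))
        y = np.array([1] * 18 + [2] * 12)
        model = grid_search_svm(X, y, c_exponents=[0], g_exponents=[0], cv_folds=3, rng_seed=0)
        report = evaluate(model, X, y)
        assert report.overall_accuracy == pytest.approx(18 / 30)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            grid_search_svm(np.zeros((5, 2)), np.ones(5, dtype=int))

    def test_grid_and_choice_reproducible(self, rng):
        X, y = self._blobs(rng, separation=2.0)
        a = grid_search_svm(X, y, c_exponents=range(-2, 3), g_exponents=range(-2, 3), rng_seed=5)
        b = grid_search_svm(X, y, c_exponents=range(-2, 3), g_exponents=range(-2, 3), rng_seed=5)
        assert (a.c, a.g) == (b.c, b.g)
        pd.testing.assert_frame_equal(a.grid_record, b.grid_record)

    def test_refinement_searches_quarter_octaves(self, rng):
        X, y = self._blobs(rng, separation=2.0)
        model = grid_search_svm(
            X, y, c_exponents=range(-1, 2), g_exponents=range(-1, 2), rng_seed=5, refine=True
        )
        assert len(model.grid_record) == 9 + 49
        # refined c/g values sit on the quarter-octave lattice
        steps = np.log2(model.grid_record["c"]) / 0.25
        assert np.abs(steps - np.round(steps)).max() < 1e-9


class TestEvaluate:
    def test_perfect_predictions_identity_confusion(self, rng):
        X, y = rng.normal(size=(20, 2)), np.array([1, 2] * 10)
        X[y == 2] += 8
        model = grid_search_svm(X, y, c_exponents=[2], g_exponents=[-2], rng_seed=0)
        report = evaluate(model, X, y)
        assert np.trace(report.confusion) == 20
        assert report.overall_percent == 100.0

    def test_counts_match_brute_force_tally(self, rng):
        truth = rng.integers(1, 4, 60)
        pred = rng.integers(1, 4, 60)
        confusion = np.zeros((3, 3), dtype=int)
        for t, p in zip(truth, pred):
            confusion[t - 1, p - 1] += 1
        report = report_from_confusion(confusion)
        assert report.confusion.sum() == 60
        np.testing.assert_array_equal(report.confusion.sum(axis=1), np.bincount(truth, minlength=4)[1:])
        assert report.overall_accuracy == pytest.approx((truth == pred).mean())

    def test_labels_outside_codes_rejected(self, rng):
        X, y = rng.normal(size=(10, 2)), np.array([1, 2] * 5)
        model = grid_search_svm(X, y, c_exponents=[0], g_exponents=[0], cv_folds=2, rng_seed=0)
        with pytest.raises(ValueError, match="1, 2, 3"):
            evaluate(model, X, np.array([1, 4] * 5))


class TestPredictObjects:
    def test_training_rows_self_consistent(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (15, 3)), rng.normal(5, 0.5, (15, 3))])
        y = np.array([1] * 15 + [3] * 15)
        model = grid_search_svm(X, y, c_exponents=[0, 4], g_exponents=[-2, 0], rng_seed=0)
        assert (predict_objects(model, X) == y).all()

    def test_single_row_prediction(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(4, 0.5, (10, 2))])
        y = np.array([1] * 10 + [2] * 10)
        model = grid_search_svm(X, y, c_exponents=[0], g_exponents=[0], rng_seed=0)
        assert predict_objects(model, np.array([4.0, 4.0])).shape == (1,)

    def test_agrees_with_decision_function_sign(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(3, 1, (20, 2))])
        y = np.array([1] * 20 + [2] * 20)
        model = grid_search_svm(X, y, c_exponents=[2], g_exponents=[-1], rng_seed=0)
        probe = rng.normal(1.5, 2.0, (30, 2))
        df = model.svc.decision_function(probe)
        np.testing.assert_array_equal(predict_objects(model, probe), np.where(df > 0, 2, 1))

    def test_feature_mismatch_rejected(self, rng):
        X, y = rng.normal(size=(10, 3)), np.array([1, 2] * 5)
        model = grid_search_svm(X, y, c_exponents=[0], g_exponents=[0], cv_folds=2, rng_seed=0)
        with pytest.raises(ValueError, match="feature count"):
            predict_objects(model, np.zeros((2, 5)))


class TestModelSerialisation:
    def test_round_trip_reproduces_predictions(self, tmp_path, rng):
        X = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(3, 1, (15, 4))])
        y = np.array([1] * 15 + [2] * 15)
        model = grid_search_svm(X, y, c_exponents=[0, 2], g_exponents=[-2, 0], rng_seed=0)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        probe = rng.normal(1.5, 2, (25, 4))
        np.testing.assert_array_equal(predict_objects(back, probe), predict_objects(model, probe))
        assert (back.c, back.g) == (model.c, model.g)
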