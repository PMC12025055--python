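"""Classifier contracts: defaults, determinism, layout guard, grid search."""

import numpy as np
import pytest

from hurstwave.errors import LayoutMismatchError, ParameterError
from hurstwave.io_formats import FeatureTable, SegmentSet, EEGSegment
from hurstwave.models import (
    FAMILY_DEFAULTS,
    ModelSpec,
    grid_search,
    predict,
    reshape_for_lstm,
    train,
)
from conftest import make_gaussian_table


@pytest.fixture(scope="module")
def separable():
    return make_gaussian_table(n_per_class=200, n_features=10, shift=3.0, seed=0)


@pytest.fixture(scope="module")
def holdout():
    return make_gaussian_table(n_per_class=50, n_features=10, shift=3.0, seed=99)


class TestModelSpec:
    def test_defaults_are_study_hyperparameters(self):
        assert FAMILY_DEFAULTS["svm"]["kernel"] == "linear"
        assert FAMILY_DEFAULTS["svm"]["class_weight"] == "balanced"
        assert FAMILY_DEFAULTS["rf"] == {
            "n_estimators": 100,
            "max_depth": 5,
            "max_features": "sqrt",
            "min_samples_split": 5,
        }
        assert FAMILY_DEFAULTS["lstm"]["units"] == 50
        assert FAMILY_DEFAULTS["lstm"]["batch_size"] == 72
        assert FAMILY_DEFAULTS["lstm"]["epochs"] == 50

    def test_unknown_family_and_hyperparameter_rejected(self):
        with pytest.raises(ParameterError):
            ModelSpec(family="xgboost")
        with pytest.raises(ParameterError):
            ModelSpec(family="rf", hyperparameters={"depth": 3})

    def test_raw_mode_lstm_only(self):
        with pytest.raises(ParameterError):
            ModelSpec(family="rf", input_mode="raw_timeseries")


class TestTrainPredict:
    def test_rf_fits_separable_data(self, separable):
        model = train(ModelSpec(family="rf", seed=0), separable)
        pred, _ = predict(model, separable)
        assert np.mean(pred == separable.labels) >= 0.98

    def test_balanced_svm_helps_minority_recall(self):
        # 90/10 imbalance with modest separation
        rng = np.random.default_rng(1)
        n0, n1 = 180, 20
        X = np.vstack(
            [rng.standard_normal((n0, 5)), rng.standard_normal((n1, 5)) + 1.0]
        )
        y = np.array([0] * n0 + [1] * n1)
        table = FeatureTable(
            [f"f{i}" for i in range(5)], X, y, [f"r{i}" for i in range(n0 + n1)]
        )
        balanced = train(ModelSpec(family="svm", seed=0), table)
        unweighted = train(
            ModelSpec(family="svm", hyperparameters={"class_weight": None}, seed=0), table
        )
        def minority_recall(model):
            pred, _ = predict(model, table)
            return np.mean(pred[y == 1] == 1)
        assert minority_recall(balanced) > minority_recall(unweighted)

    @pytest.mark.parametrize("family", ["svm", "rf"])
    def test_same_seed_identical_predictions(self, family, separable, holdout):
        a = train(ModelSpec(family=family, seed=3), separable)
        b = train(ModelSpec(family=family, seed=3), separable)
        pa, sa = predict(a, holdout)
        pb, sb = predict(b, holdout)
        np.testing.assert_array_equal(pa, pb)
        np.testing.assert_array_equal(sa, sb)

    def test_scores_in_unit_interval_and_threshold(self, separable, holdout):
        model = train(ModelSpec(family="rf", seed=0), separable)
        pred, scores = predict(model, holdout)
        assert np.all((scores >= 0) & (scores <= 1))
        np.testing.assert_array_equal(pred, (scores >= 0.5).astype(int))

    def test_empty_input_empty_output(self, separable):
        model = train(ModelSpec(family="rf", seed=0), separable)
        empty = FeatureTable(separable.feature_names, np.empty((0, 10)), [], [])
        pred, scores = predict(model, empty)
        assert pred.size == 0 and scores.size == 0

    def test_layout_mismatch_names_features(self, separable):
        model = train(ModelSpec(family="rf", seed=0), separable)
        other = make_gaussian_table(n_per_class=5, n_features=8, seed=2)
        with pytest.raises(LayoutMismatchError, match="f9"):
            predict(model, other)

    def test_single_class_rejected(self):
        table = FeatureTable(
            ["f0"], np.random.default_rng(0).standard_normal((6, 1)), [0] * 6, list("abcdef")
        )
        with pytest.raises(ParameterError):
            train(ModelSpec(family="rf"), table)

    def test_rf_respects_max_depth(self, separable):
        model = train(ModelSpec(family="rf", seed=0), separable)
        assert all(t.get_depth() <= 5 for t in model.estimator.estimators_)

    def test_linear_svm_has_one_weight_per_feature(self, separable):
        model = train(ModelSpec(family="svm", seed=0), separable)
        assert model.estimator.coef_.shape == (1, separable.n_features)


class TestLstm:
    def test_learns_separable_features(self, separable, holdout):
        model = train(ModelSpec(family="lstm", seed=0), separable)
        pred, _ = predict(model, holdout)
        assert np.mean(pred == holdout.labels) >= 0.85

    def test_deterministic_given_seed(self, separable, holdout):
        a = train(ModelSpec(family="lstm", seed=1), separable)
        b = train(ModelSpec(family="lstm", seed=1), separable)
        _, sa = predict(a, holdout)
        _, sb = predict(b, holdout)
        np.testing.assert_array_equal(sa, sb)

    def test_scores_are_probabilities(self, separable, holdout):
        model = train(ModelSpec(family="lstm", seed=0), separable)
        _, scores = predict(model, holdout)
        assert np.all((scores >= 0) & (scores <= 1))


class TestReshapeForLstm:
    def test_features_mode_shape(self, separable):
        assert reshape_for_lstm(separable, "features").shape == (400, 1, 10)

    def test_raw_mode_shape(self):
        segs = SegmentSet(
            [
                EEGSegment(np.random.default_rng(i).standard_normal(512), fs=173.61,
                           label=i % 2, segment_id=f"s{i}")
                for i in range(4)
            ]
        )
        assert reshape_for_lstm(segs, "raw_timeseries").shape == (4, 512, 1)

    def test_mixed_lengths_rejected(self):
        segs = SegmentSet(
            [
                EEGSegment(np.zeros(128) + np.arange(128), fs=1.0, segment_id="a"),
                EEGSegment(np.arange(64.0), fs=1.0, segment_id="b"),
            ]
        )
        with pytest.raises(ParameterError, match="lengths"):
            reshape_for_lstm(segs, "raw_timeseries")

    def test_features_round_trip(self, separable):
        arr = reshape_for_lstm(separable, "features")
        np.testing.assert_array_equal(arr[:, 0, :], separable.matrix)


class TestGridSearch:
    def test_single_point_returned(self, separable):
        spec, cv_table = grid_search("rf", {"max_depth": [5]}, separable, folds=3, seed=0)
        assert spec.hyperparameters == {"max_depth": 5}
        assert len(cv_table) == 1

    def test_cv_table_is_grid_product(self, separable):
        _, cv_table = grid_search(
            "rf",
            {"max_depth": [2, 5], "n_estimators": [10, 20, 30]},
            separable,
            folds=3,
            seed=0,
        )
        assert len(cv_table) == 6

    def test_invalid_hyperparameter_rejected_before_training(self, separable):
        with pytest.raises(ParameterError):
            grid_search("rf", {"bogus": [1]}, separable, folds=3)

    def test_depth_five_wins_on_interaction_data(self):
        """Depth-1 stumps cannot express a 3-feature interaction; depth 5 can,
        so the search should prefer it for most seeds."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 2, size=(200, 3)).astype(float)
            y = (X.sum(axis=1) % 2).astype(int)  # parity: pure interaction
            X += 0.05 * rng.standard_normal(X.shape)
            table = FeatureTable(
                ["a", "b", "c"], X, y, [f"r{i}" for i in range(200)]
            )
            spec, _ = grid_search(
                "rf", {"max_depth": [1, 5]}, table, folds=5, seed=seed
            )
            wins += spec.hyperparameters["max_depth"] == 5
        assert wins >= 0.8 * n_seeds


class TestRawTimeseriesLstm:
    def test_learns_amplitude_difference_on_short_epochs(self):
        """Raw mode: one feature per timestep. Classes differ in amplitude,
        which even a briefly trained recurrent net should separate."""
        from hurstwave.models import train_raw_lstm

        rng = np.random.default_rng(0)
        segs = []
        for i in range(40):
            label = i % 2
            amp = 0.3 if label == 0 else 1.5
            segs.append(
                EEGSegment(
                    amp * rng.standard_normal(64),
                    fs=64.0,
                    label=label,
                    segment_id=f"s{i}",
                )
            )
        segset = SegmentSet(segs)
        spec = ModelSpec(
            family="lstm",
            hyperparameters={"units": 8, "epochs": 30, "batch_size": 8,
                             "learning_rate": 1e-2},
            seed=0,
            input_mode="raw_timeseries",
        )
        model = train_raw_lstm(spec, segset)
        scores = model.estimator.predict_proba(
            reshape_for_lstm(segset, "raw_timeseries")
        )
        acc = np.mean((scores >= 0.5).astype(int) == segset.labels.astype(int))
        assert acc >= 0.8
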