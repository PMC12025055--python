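"""The three classifiers and their grid search.

Defaults are the study hyperparameters:

* SVM — linear kernel, probability estimates on, balanced class weights;
* random forest — 100 trees, max depth 5, sqrt feature sampling,
  min_samples_split 5;
* LSTM — 50 units, dropout 0.1, dense(1, sigmoid), binary cross-entropy,
  RMSProp, 50 epochs, batch size 72 (NumPy implementation, see
  :mod:`hurstwave._lstm`).

The LSTM accepts either the 47-feature vector (one timestep) or raw
time-series segments (one feature per timestep).
"""

from __future__ import annotations

import itertools
import warnings
import time
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._lstm import NumpyLSTM
from .errors import LayoutMismatchError, ParameterError
from .io_formats import FeatureTable, SegmentSet

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "train",
    "predict",
    "grid_search",
    "reshape_for_lstm",
    "FAMILY_DEFAULTS",
]

FAMILY_DEFAULTS: dict[str, dict[str, Any]] = {
    "svm": {"kernel": "linear", "probability": True, "class_weight": "balanced", "C": 1.0},
    "rf": {
        "n_estimators": 100,
        "max_depth": 5,
        "max_features": "sqrt",
        "min_samples_split": 5,
    },
    "lstm": {
        "units": 50,
        "dropout": 0.1,
        "epochs": 50,
        "batch_size": 72,
        "learning_rate": 1e-3,
    },
}

#: Decision threshold on the class-1 score.
SCORE_THRESHOLD = 0.5


@dataclass(frozen=True)
class ModelSpec:
    """Family, hyperparameters and seed for one classifier."""

    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0
    input_mode: str = "features"  # lstm only: "features" | "raw_timeseries"

    def __post_init__(self) -> None:
        if self.family not in FAMILY_DEFAULTS:
            raise ParameterError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILY_DEFAULTS)}"
            )
        unknown = set(self.hyperparameters) - set(FAMILY_DEFAULTS[self.family])
        if unknown:
            raise ParameterError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}"
            )
        if self.input_mode not in ("features", "raw_timeseries"):
            raise ParameterError(f"invalid input_mode {self.input_mode!r}")
        if self.input_mode == "raw_timeseries" and self.family != "lstm":
            raise ParameterError("raw_timeseries input is only supported by the lstm family")

    def resolved(self) -> dict[str, Any]:
        """Hyperparameters with family defaults filled in."""
        return {**FAMILY_DEFAULTS[self.family], **dict(self.hyperparameters)}


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature layout it was trained on."""

    spec: ModelSpec
    estimator: Any
    feature_names: list[str]
    n_rows: int
    class_balance: dict[int, int]
    train_seconds: float

    def _check_layout(self, table: FeatureTable) -> None:
        if table.feature_names != self.feature_names:
            missing = [n for n in self.feature_names if n not in table.feature_names]
            extra = [n for n in table.feature_names if n not in self.feature_names]
            raise LayoutMismatchError(
                f"feature layout mismatch: missing {missing}, unexpected {extra}"
            )


def reshape_for_lstm(data: FeatureTable | SegmentSet, mode: str = "features") -> np.ndarray:
    """3-axis (samples × timesteps × features) array for recurrent input.

    ``features`` mode: each row becomes one timestep carrying the whole
    feature vector. ``raw_timeseries`` mode: each segment's samples become
    the timesteps with one feature per step; all segments must share a length.
    """
    if mode == "features":
        if not isinstance(data, FeatureTable):
            raise ParameterError("features mode expects a FeatureTable")
        return data.matrix[:, None, :]
    if mode == "raw_timeseries":
        if not isinstance(data, SegmentSet):
            raise ParameterError("raw_timeseries mode expects a SegmentSet")
        lengths = {s.n_samples for s in data}
        if len(lengths) > 1:
            raise ParameterError(f"mixed segment lengths in raw mode: {sorted(lengths)}")
        return np.stack([s.samples for s in data])[:, :, None]
    raise ParameterError(f"unknown mode {mode!r}")


def _build_estimator(spec: ModelSpec, n_features: int):
    hp = spec.resolved()
    if spec.family == "svm":
        return SVC(random_state=spec.seed, **hp)
    if spec.family == "rf":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    return NumpyLSTM(n_features=n_features, seed=spec.seed, **hp)


def train(spec: ModelSpec, table: FeatureTable) -> TrainedModel:
    """Fit one classifier on a feature table.

    SVM/RF fits are deterministic given the seed; the LSTM is deterministic
    too (NumPy RNG) but its accuracy is assessed with tolerance bands since
    small training changes move it more than the convex models.
    """
    y = table.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ParameterError("need at least 2 rows in each of the two classes")
    if table.matrix.shape[0] != y.size:
        raise ParameterError("feature/label length mismatch")

    est = _build_estimator(spec, table.n_features)
    t0 = time.perf_counter()
    if spec.family == "lstm":
        est.fit(reshape_for_lstm(table, "features"), y)
    else:
        with warnings.catch_warnings():
            # sklearn >= 1.9 deprecation chatter about SVC(probability=True);
            # the setting is deliberate and still functional
            warnings.filterwarnings("ignore", category=FutureWarning)
            est.fit(table.matrix, y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=list(table.feature_names),
        n_rows=table.n_rows,
        class_balance={int(c): int(n) for c, n in zip(classes, counts)},
        train_seconds=time.perf_counter() - t0,
    )


def train_raw_lstm(spec: ModelSpec, segments: SegmentSet) -> TrainedModel:
    """Fit the LSTM directly on raw time-series segments (one feature/step)."""
    if spec.family != "lstm" or spec.input_mode != "raw_timeseries":
        raise ParameterError("train_raw_lstm requires an lstm spec in raw_timeseries mode")
    X = reshape_for_lstm(segments, "raw_timeseries")
    y = segments.labels.astype(int)
    est = NumpyLSTM(n_features=1, seed=spec.seed, **spec.resolved())
    t0 = time.perf_counter()
    est.fit(X, y)
    classes, counts = np.unique(y, return_counts=True)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=["raw"],
        n_rows=len(segments),
        class_balance={int(c): int(n) for c, n in zip(classes, counts)},
        train_seconds=time.perf_counter() - t0,
    )


def predict(model: TrainedModel, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class-1 scores for a table with the training layout.

    The label is 1 exactly when the score reaches :data:`SCORE_THRESHOLD`.
    """
    model._check_layout(table)
    if table.n_rows == 0:
        return np.empty(0, dtype=int), np.empty(0)
    if model.spec.family == "lstm":
        scores = model.estimator.predict_proba(reshape_for_lstm(table, "features"))
    elif model.spec.family == "svm":
        # logistic squashing of the signed margin: the 0.5 threshold then
        # coincides with the (class-weighted) decision boundary, which Platt
        # recalibration would shift; calibrated probabilities stay available
        # on the fitted estimator
        margin = model.estimator.decision_function(table.matrix)
        scores = 1.0 / (1.0 + np.exp(-margin))
    else:
        proba = model.estimator.predict_proba(table.matrix)
        scores = proba[:, list(model.estimator.classes_).index(1)]
    labels = (scores >= SCORE_THRESHOLD).astype(int)
    return labels, scores


def grid_search(
    family: str,
    grid: Mapping[str, Sequence[Any]],
    table: FeatureTable,
    folds: int = 10,
    seed: int = 0,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive hyperparameter search by stratified k-fold mean accuracy.

    Every grid point is validated against the family's hyperparameter names
    before any training starts. Ties keep the first point in grid order.
    Returns the winning spec and the full CV table.
    """
    if not grid:
        raise ParameterError("empty grid")
    unknown = set(grid) - set(FAMILY_DEFAULTS[family]) if family in FAMILY_DEFAULTS else set(grid)
    if family not in FAMILY_DEFAULTS:
        raise ParameterError(f"unknown family {family!r}")
    if unknown:
        raise ParameterError(f"unknown hyperparameters for {family}: {sorted(unknown)}")

    names = list(grid)
    rows = []
    best_spec, best_acc = None, -np.inf
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for values in itertools.product(*(grid[n] for n in names)):
        hp = dict(zip(names, values))
        spec = ModelSpec(family=family, hyperparameters=hp, seed=seed)
        accs = []
        for train_idx, test_idx in skf.split(table.matrix, table.labels):
            sub_train = FeatureTable(
                table.feature_names,
                table.matrix[train_idx],
                table.labels[train_idx],
                [table.row_ids[i] for i in train_idx],
            )
            sub_test = FeatureTable(
                table.feature_names,
                table.matrix[test_idx],
                table.labels[test_idx],
                [table.row_ids[i] for i in test_idx],
            )
            fitted = train(spec, sub_train)
            pred, _ = predict(fitted, sub_test)
            accs.append(float(np.mean(pred == sub_test.labels)))
        mean_acc = float(np.mean(accs))
        rows.append({**hp, "mean_accuracy": mean_acc})
        if mean_acc > best_acc:  # strict: ties keep the earlier grid point
            best_acc, best_spec = mean_acc, spec
    return best_spec, pd.DataFrame(rows)
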