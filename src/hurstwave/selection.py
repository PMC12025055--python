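"""Feature selection and importance ranking.

Two selectors are provided — a one-way ANOVA F-test and impurity-based
importances from a random-forest regressor on the 0/1 label — plus an
L2-logistic-regression importance ranking (absolute standardized
coefficients). The classification pipeline runs with selection *disabled* by
default: on this problem all 47 features feed the classifier, and selection
is an opt-in stage for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .errors import EstimationError, ParameterError
from .io_formats import FeatureTable

__all__ = [
    "SelectionResult",
    "ImportanceRanking",
    "anova_f",
    "rf_regression_select",
    "logistic_importance",
]

DEFAULT_TOP_K = 20


@dataclass
class SelectionResult:
    """Scores and the ordered top-k feature names for one selector."""

    method: str
    scores: dict[str, float]
    selected: list[str]
    k: int


@dataclass
class ImportanceRanking:
    """Feature → importance magnitude, with the ordered top-m list."""

    importances: dict[str, float]
    top: list[str] = field(default_factory=list)


def _check_two_classes(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ParameterError("feature table must contain both classes")
    if np.sum(y == 0) < 2 or np.sum(y == 1) < 2:
        raise ParameterError("each class needs at least 2 rows")
    return table.matrix, y


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature one-way F statistics via explicit SS decomposition.

    F = MS_between / MS_within with (1, N−2) degrees of freedom for two
    groups. When both the between- and within-class sums of squares vanish
    (a constant feature) F is defined as 0.
    """
    x0, x1 = X[y == 0], X[y == 1]
    n0, n1 = len(x0), len(x1)
    grand = X.mean(axis=0)
    ssb = n0 * (x0.mean(axis=0) - grand) ** 2 + n1 * (x1.mean(axis=0) - grand) ** 2
    ssw = ((x0 - x0.mean(axis=0)) ** 2).sum(axis=0) + ((x1 - x1.mean(axis=0)) ** 2).sum(axis=0)
    df_within = n0 + n1 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / df_within)
    f = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    return f


def anova_f(table: FeatureTable, k: int = DEFAULT_TOP_K) -> SelectionResult:
    """ANOVA F-test selection: keep the k features with the largest F."""
    X, y = _check_two_classes(table)
    f = anova_f_scores(X, y)
    order = np.argsort(-f, kind="stable")
    k_eff = min(k, table.n_features)
    return SelectionResult(
        method="anova",
        scores=dict(zip(table.feature_names, f.tolist())),
        selected=[table.feature_names[i] for i in order[:k_eff]],
        k=k_eff,
    )


def rf_regression_select(
    table: FeatureTable,
    k: int = DEFAULT_TOP_K,
    seed: int = 0,
    n_estimators: int = 100,
) -> SelectionResult:
    """Impurity importances from a random forest regressing the 0/1 label."""
    X, y = _check_two_classes(table)
    forest = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(X, y.astype(float))
    imp = forest.feature_importances_
    order = np.argsort(-imp, kind="stable")
    k_eff = min(k, table.n_features)
    return SelectionResult(
        method="rf_regression",
        scores=dict(zip(table.feature_names, imp.tolist())),
        selected=[table.feature_names[i] for i in order[:k_eff]],
        k=k_eff,
    )


def logistic_importance(
    table: FeatureTable, top_m: int = 15, max_iter: int = 1000
) -> ImportanceRanking:
    """|standardized coefficient| importance from an L2 logistic fit.

    Features are standardized internally so coefficient magnitudes are
    comparable across features.
    """
    import warnings

    X, y = _check_two_classes(table)
    Xs = StandardScaler().fit_transform(X)
    model = LogisticRegression(max_iter=max_iter, solver="lbfgs")  # default L2 penalty
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(Xs, y)
        except ConvergenceWarning as exc:
            raise EstimationError(
                f"logistic regression did not converge in {max_iter} iterations"
            ) from exc
    mags = np.abs(model.coef_[0])
    order = np.argsort(-mags, kind="stable")
    m_eff = min(top_m, table.n_features)
    return ImportanceRanking(
        importances=dict(zip(table.feature_names, mags.tolist())),
        top=[table.feature_names[i] for i in order[:m_eff]],
    )
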