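"""Cross-validation, confusion-matrix metrics, bootstrap CIs, effect sizes.

Conventions: class 1 (seizure) is the positive class; sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP), FPR = FP/(FP+TN) = 1 − specificity.
The k-fold summary is the plain arithmetic mean of the per-fold metric
values. 95% intervals come from B bootstrap resamples of the held-out
prediction/label pairs, reported both as the 2.5/97.5 percentile interval
and as the normal approximation μ ± 1.96σ. Cohen's d uses the pooled
sample standard deviation.
"""

from __future__ import annotations

import time
import tracemalloc
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError
from .io_formats import FeatureTable
from . import models as _models

__all__ = [
    "EvalReport",
    "CVResult",
    "CIEntry",
    "EffectSize",
    "TimingRecord",
    "confusion_metrics",
    "crossval",
    "roc_auc",
    "bootstrap_ci",
    "normal_ci",
    "cohens_d",
    "timing_profile",
]

Z_95 = 1.96


@dataclass
class EvalReport:
    """Binary-classification metrics derived from a confusion matrix."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    support: dict[int, int]
    auc: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("precision", "recall", "f1", "support"):
            d[key] = {str(k): v for k, v in d[key].items()}
        return d


@dataclass
class CVResult:
    """Per-fold metrics and their arithmetic mean."""

    fold_reports: list[EvalReport]
    fold_assignments: np.ndarray  # row index -> fold index
    metrics_avg: dict[str, float]

    @property
    def fold_accuracies(self) -> list[float]:
        return [r.accuracy for r in self.fold_reports]


@dataclass
class CIEntry:
    """One 95% confidence interval for a metric."""

    metric: str
    point: float
    lower: float
    upper: float
    method: str  # "percentile" | "normal"
    B: int
    mu: float
    sigma: float
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ParameterError("CI lower bound exceeds upper bound")


@dataclass
class EffectSize:
    """Cohen's d between two groups, with the pooled SD decomposition."""

    d: float
    mean0: float
    mean1: float
    sd0: float
    sd1: float
    n0: int
    n1: int
    s_pooled: float
    infinite: bool = False


@dataclass
class TimingRecord:
    stage: str
    seconds: float
    peak_memory_mb: float


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> EvalReport:
    """All confusion-matrix metrics with seizure (1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ParameterError("empty input")
    if y_true.shape != y_pred.shape:
        raise ParameterError("y_true and y_pred lengths differ")
    if not (np.all(np.isin(y_true, [0, 1])) and np.all(np.isin(y_pred, [0, 1]))):
        raise ParameterError("labels must be binary 0/1")

    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    precision = {1: _safe_div(tp, tp + fp), 0: _safe_div(tn, tn + fn)}
    recall = {1: _safe_div(tp, tp + fn), 0: _safe_div(tn, tn + fp)}
    f1 = {
        c: _safe_div(2 * precision[c] * recall[c], precision[c] + recall[c])
        for c in (0, 1)
    }
    return EvalReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=(tp + tn) / y_true.size,
        sensitivity=recall[1],
        specificity=recall[0],
        fpr=_safe_div(fp, fp + tn),
        precision=precision,
        recall=recall,
        f1=f1,
        support={1: int(np.sum(y_true == 1)), 0: int(np.sum(y_true == 0))},
    )


def macro_metrics(report: EvalReport) -> dict[str, float]:
    """Single-value (macro-averaged) precision/recall/F1 summary."""
    return {
        "precision": float(np.mean([report.precision[0], report.precision[1]])),
        "recall": float(np.mean([report.recall[0], report.recall[1]])),
        "f1": float(np.mean([report.f1[0], report.f1[1]])),
    }


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------

def crossval(
    model_spec: "_models.ModelSpec",
    table: FeatureTable,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV; the summary is the exact mean of the fold values."""
    y = table.labels
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < k:
        raise ParameterError(
            f"k={k} exceeds the smaller class count {counts.min() if len(counts) else 0}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[EvalReport] = []
    assignment = np.full(table.n_rows, -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(table.matrix, y)):
        assignment[test_idx] = fold
        sub_train = FeatureTable(
            table.feature_names,
            table.matrix[train_idx],
            y[train_idx],
            [table.row_ids[i] for i in train_idx],
        )
        sub_test = FeatureTable(
            table.feature_names,
            table.matrix[test_idx],
            y[test_idx],
            [table.row_ids[i] for i in test_idx],
        )
        fitted = _models.train(model_spec, sub_train)
        pred, scores = _models.predict(fitted, sub_test)
        rep = confusion_metrics(sub_test.labels, pred)
        if len(np.unique(sub_test.labels)) == 2:
            rep.auc = float(roc_auc_score(sub_test.labels, scores))
        reports.append(rep)

    metrics_avg = {
        "accuracy": float(np.mean([r.accuracy for r in reports])),
        "sensitivity": float(np.mean([r.sensitivity for r in reports])),
        "specificity": float(np.mean([r.specificity for r in reports])),
        "fpr": float(np.mean([r.fpr for r in reports])),
    }
    for c in (0, 1):
        metrics_avg[f"precision_{c}"] = float(np.mean([r.precision[c] for r in reports]))
        metrics_avg[f"recall_{c}"] = float(np.mean([r.recall[c] for r in reports]))
        metrics_avg[f"f1_{c}"] = float(np.mean([r.f1[c] for r in reports]))
    aucs = [r.auc for r in reports if r.auc is not None]
    if aucs:
        metrics_avg["auc"] = float(np.mean(aucs))
    return CVResult(fold_reports=reports, fold_assignments=assignment, metrics_avg=metrics_avg)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the empirical ROC curve points (fpr, tpr).

    Trapezoidal integration over the empirical curve; rank-averaged tie
    handling (equivalently the normalised Mann–Whitney U count).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ParameterError("both classes must be present for ROC analysis")
    if not np.all(np.isfinite(scores)):
        raise ParameterError("scores must be finite")
    auc = float(roc_auc_score(y_true, scores))
    fpr, tpr, _ = roc_curve(y_true, scores)
    return auc, fpr, tpr


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

def normal_ci(mu: float, sigma: float) -> tuple[float, float]:
    """Normal-approximation 95% interval μ ± 1.96σ."""
    return mu - Z_95 * sigma, mu + Z_95 * sigma


def bootstrap_ci(
    y_true: Sequence[int],
    y_pred_or_scores: Sequence[float],
    metric: Callable[[np.ndarray, np.ndarray], float],
    metric_name: str = "metric",
    B: int = 1000,
    seed: int = 0,
    max_redraws: int = 10_000,
) -> dict[str, CIEntry]:
    """Percentile and normal 95% CIs from B resamples of (label, prediction) pairs.

    Each replicate resamples row indices with replacement at the original
    size. Replicates on which the metric is undefined (e.g. a single class
    drawn) are redrawn and counted. Models are never refitted.
    """
    if B < 100:
        raise ParameterError("B must be >= 100")
    y_true = np.asarray(y_true)
    y_other = np.asarray(y_pred_or_scores)
    n = y_true.size
    point = float(metric(y_true, y_other))
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            values[b] = metric(y_true[idx], y_other[idx])
        except (ParameterError, ValueError):
            redrawn += 1
            if redrawn > max_redraws:
                raise ParameterError(
                    f"metric undefined on >{max_redraws} bootstrap replicates"
                )
            continue
        b += 1
    mu = float(np.mean(values))
    sigma = float(np.std(values, ddof=1))
    p_lo, p_hi = np.percentile(values, [2.5, 97.5])
    n_lo, n_hi = normal_ci(mu, sigma)
    common = dict(metric=metric_name, point=point, B=B, mu=mu, sigma=sigma, n_redrawn=redrawn)
    return {
        "percentile": CIEntry(lower=float(p_lo), upper=float(p_hi), method="percentile", **common),
        "normal": CIEntry(lower=n_lo, upper=n_hi, method="normal", **common),
    }


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

def cohens_d(values0: Sequence[float], values1: Sequence[float]) -> EffectSize:
    """Cohen's d = (x̄0 − x̄1) / S_pooled with pooled sample SDs.

    When both groups are constant (S_pooled = 0): d = 0 for equal means,
    otherwise the infinite-effect flag is set and d is ±inf.
    """
    v0 = np.asarray(values0, dtype=float)
    v1 = np.asarray(values1, dtype=float)
    if v0.size < 2 or v1.size < 2:
        raise ParameterError("each group needs at least 2 values")
    n0, n1 = v0.size, v1.size
    m0, m1 = float(np.mean(v0)), float(np.mean(v1))
    s0, s1 = float(np.std(v0, ddof=1)), float(np.std(v1, ddof=1))
    s_pooled = float(
        np.sqrt(((n0 - 1) * s0**2 + (n1 - 1) * s1**2) / (n0 + n1 - 2))
    )
    if s_pooled == 0.0:
        if m0 == m1:
            d, infinite = 0.0, False
        else:
            d, infinite = float(np.sign(m0 - m1)) * np.inf, True
    else:
        d, infinite = (m0 - m1) / s_pooled, False
    return EffectSize(
        d=d, mean0=m0, mean1=m1, sd0=s0, sd1=s1, n0=n0, n1=n1,
        s_pooled=s_pooled, infinite=infinite,
    )


# ---------------------------------------------------------------------------
# timing instrumentation
# ---------------------------------------------------------------------------

@contextmanager
def timing_profile(stage: str, records: list[TimingRecord] | None = None, enabled: bool = True):
    """Record wall time and peak memory of a pipeline stage.

    Values are reported for information only — no assertion anywhere depends
    on them. With ``enabled=False`` the block runs with zero overhead.
    """
    if not enabled:
        yield None
        return
    tracing_before = tracemalloc.is_tracing()
    if not tracing_before:
        tracemalloc.start()
    tracemalloc.reset_peak()
    t0 = time.perf_counter()
    try:
        yield None
    finally:
        elapsed = time.perf_counter() - t0
        _, peak = tracemalloc.get_traced_memory()
        if not tracing_before:
            tracemalloc.stop()
        if records is not None:
            records.append(
                TimingRecord(stage=stage, seconds=elapsed, peak_memory_mb=peak / 2**20)
            )
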