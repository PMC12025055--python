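"""Metric identities, AUC oracle, bootstrap coverage, effect sizes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hurstwave.errors import ParameterError
from hurstwave.evaluate import (
    TimingRecord,
    bootstrap_ci,
    cohens_d,
    confusion_metrics,
    crossval,
    normal_ci,
    roc_auc,
    timing_profile,
)
from hurstwave.models import ModelSpec
from conftest import make_gaussian_table


def pairwise_auc(y, s):
    """Brute-force Mann–Whitney oracle: fraction of (neg, pos) pairs ranked
    correctly, ties counted half."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_worked_example(self):
        y_true = np.array([1] * 100 + [0] * 100)
        y_pred = np.array([1] * 98 + [0] * 2 + [1] * 3 + [0] * 97)
        rep = confusion_metrics(y_true, y_pred)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (98, 97, 3, 2)
        assert rep.accuracy == pytest.approx(0.975)
        assert rep.sensitivity == pytest.approx(0.98)
        assert rep.specificity == pytest.approx(0.97)
        assert rep.fpr == pytest.approx(0.03)

    def test_perfect_and_allwrong(self):
        y = np.array([0, 1, 0, 1])
        perfect = confusion_metrics(y, y)
        assert perfect.accuracy == 1.0 and perfect.fpr == 0.0
        wrong = confusion_metrics(y, 1 - y)
        assert wrong.accuracy == 0.0
        assert wrong.sensitivity == 0.0 and wrong.specificity == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            confusion_metrics([], [])

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=60)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_identities_on_random_inputs(self, pairs):
        y_true = np.array([p[0] for p in pairs])
        y_pred = np.array([p[1] for p in pairs])
        rep = confusion_metrics(y_true, y_pred)
        if np.any(y_true == 0):  # identity needs the negative class present
            assert rep.fpr + rep.specificity == pytest.approx(1.0)
        for c in (0, 1):
            p, r = rep.precision[c], rep.recall[c]
            expected_f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
            assert rep.f1[c] == pytest.approx(expected_f1)
        assert rep.accuracy == pytest.approx(
            (rep.tp + rep.tn) / (rep.tp + rep.tn + rep.fp + rep.fn)
        )


class TestCrossval:
    def test_average_is_exact_fold_mean(self, gaussian_table):
        cv = crossval(ModelSpec(family="rf", seed=0), gaussian_table, k=10, seed=0)
        assert cv.metrics_avg["accuracy"] == np.mean(cv.fold_accuracies)
        assert len(cv.fold_reports) == 10

    def test_every_row_tested_once(self, gaussian_table):
        cv = crossval(ModelSpec(family="rf", seed=0), gaussian_table, k=10, seed=0)
        assert np.all(cv.fold_assignments >= 0)
        counts = np.bincount(cv.fold_assignments)
        assert counts.max() - counts.min() <= 1  # stratified, near-equal folds

    def test_separable_rf_accuracy(self, gaussian_table):
        cv = crossval(ModelSpec(family="rf", seed=0), gaussian_table, k=10, seed=0)
        assert cv.metrics_avg["accuracy"] >= 0.90

    def test_k_exceeding_class_count_rejected(self):
        small = make_gaussian_table(n_per_class=5)
        with pytest.raises(ParameterError):
            crossval(ModelSpec(family="rf"), small, k=10)

    def test_constant_model_scores_majority_fraction(self, monkeypatch):
        """A model that always predicts class 0 must score exactly the
        majority-class fraction of each fold."""
        from hurstwave import evaluate as ev

        class _Const:
            pass

        def fake_train(spec, table):
            return _Const()

        def fake_predict(model, table):
            n = table.n_rows
            return np.zeros(n, dtype=int), np.zeros(n)

        monkeypatch.setattr(ev._models, "train", fake_train)
        monkeypatch.setattr(ev._models, "predict", fake_predict)
        table = make_gaussian_table(n_per_class=30)
        cv = crossval(ModelSpec(family="rf"), table, k=10, seed=0)
        # every stratified fold is 3 vs 3 -> accuracy exactly 0.5 per fold
        assert cv.metrics_avg["accuracy"] == 0.5


class TestRocAuc:
    def test_scores_equal_labels(self):
        y = np.array([0, 1, 1, 0, 1])
        auc, _, _ = roc_auc(y, y.astype(float))
        assert auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(50):
            y = np.array([0] * 50 + [1] * 50)
            s = rng.permutation(np.linspace(0, 1, 100))
            aucs.append(roc_auc(y, s)[0])
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(6, 30)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # rounding forces ties
            auc, _, _ = roc_auc(y, s)
            assert auc == pytest.approx(pairwise_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc(np.ones(5, dtype=int), np.random.rand(5))


class TestBootstrapCI:
    @staticmethod
    def _accuracy(yt, yp):
        return float(np.mean(yt == yp))

    def test_constant_metric_zero_width(self):
        y = np.array([0, 1] * 50)
        cis = bootstrap_ci(y, y, self._accuracy, B=200, seed=0)
        assert cis["percentile"].lower == cis["percentile"].upper == 1.0

    def test_normal_interval_arithmetic(self):
        lo, hi = normal_ci(0.97, 0.01)
        assert (lo, hi) == pytest.approx((0.9504, 0.9896))

    def test_coverage_of_point_estimate(self):
        """The 95% percentile interval should contain the full-sample point
        estimate for the vast majority of simulated datasets."""
        rng = np.random.default_rng(2)
        hits = 0
        for i in range(100):
            y = rng.integers(0, 2, 100)
            yp = np.where(rng.random(100) < 0.9, y, 1 - y)  # ~90% accuracy
            cis = bootstrap_ci(y, yp, self._accuracy, B=200, seed=i)
            e = cis["percentile"]
            hits += e.lower <= e.point <= e.upper
        assert hits >= 90

    def test_undefined_replicates_redrawn_and_counted(self):
        y = np.array([0] * 19 + [1])  # single positive: many degenerate draws
        s = np.linspace(0, 1, 20)
        cis = bootstrap_ci(
            y, s, lambda yt, sc: roc_auc(yt, sc)[0], B=100, seed=0
        )
        assert cis["percentile"].n_redrawn > 0

    def test_small_B_rejected(self):
        with pytest.raises(ParameterError):
            bootstrap_ci(np.zeros(4, int), np.zeros(4, int), self._accuracy, B=10)


class TestCohensD:
    def test_hand_computed_example(self):
        es = cohens_d([1, 2, 3], [3, 4, 5])
        assert es.mean0 == 2 and es.mean1 == 4
        assert es.s_pooled == pytest.approx(1.0)
        assert abs(es.d) == pytest.approx(2.0)

    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]).d == 0.0

    def test_swap_negates(self):
        a = cohens_d([1, 2, 3], [3, 4, 5])
        b = cohens_d([3, 4, 5], [1, 2, 3])
        assert a.d == -b.d and abs(a.d) == abs(b.d)

    def test_constant_groups_unequal_means(self):
        es = cohens_d([2.0, 2.0], [5.0, 5.0])
        assert es.infinite and np.isinf(es.d)

    def test_constant_groups_equal_means(self):
        es = cohens_d([2.0, 2.0], [2.0, 2.0])
        assert es.d == 0.0 and not es.infinite


class TestTimingProfile:
    def test_records_nonnegative(self):
        records: list[TimingRecord] = []
        with timing_profile("stage_a", records):
            sum(range(10000))
        assert len(records) == 1
        assert records[0].seconds >= 0 and records[0].peak_memory_mb >= 0

    def test_disabled_adds_nothing(self):
        records: list[TimingRecord] = []
        with timing_profile("stage_a", records, enabled=False):
            pass
        assert records == []

    def test_stage_records_sum_below_total(self):
        records: list[TimingRecord] = []
        import time

        t0 = time.perf_counter()
        for name in ("a", "b"):
            with timing_profile(name, records):
                sum(range(20000))
        total = time.perf_counter() - t0
        assert sum(r.seconds for r in records) <= total + 0.05
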