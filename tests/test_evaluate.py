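"""Tests of LOOCV, the accuracy metric, per-class metrics and the
Wilcoxon signed-rank comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.dummy import DummyClassifier

from spastimu import (
    accuracy,
    loocv,
    make_classifier,
    median_accuracy,
    per_class_metrics,
    run_condition_grid,
    wilcoxon_compare,
)


def _table(labels, subjects, feature_values=None, scheme="nonoverlap"):
    labels = np.asarray(labels)
    if feature_values is None:
        feature_values = labels.astype(float)
    f0 = np.asarray(feature_values, float)
    # a second, non-collinear feature with a small deterministic wiggle
    f1 = 2.0 * f0 + 0.01 * np.cos(np.arange(f0.size, dtype=float))
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "mas_label": labels,
            "scheme": scheme,
            "f0": f0,
            "f1": f1,
        }
    )


class TestAccuracy:
    def test_all_match(self):
        assert accuracy([0, 1, 2], [0, 1, 2]) == 1.0

    def test_none_match(self):
        assert accuracy([0, 1, 2], [1, 2, 0]) == 0.0

    def test_partial(self):
        assert accuracy([0, 0, 1, 2], [0, 1, 1, 1]) == 0.5

    def test_errors(self):
        with pytest.raises(ValueError):
            accuracy([0, 1], [0])
        with pytest.raises(ValueError):
            accuracy([], [])


class TestMedian:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.7, 0.8, 0.9], 0.8), ([0.6, 0.8], 0.7), ([0.42], 0.42)],
    )
    def test_median(self, values, expected):
        assert median_accuracy(values) == pytest.approx(expected)

    def test_empty(self):
        with pytest.raises(ValueError):
            median_accuracy([])


def _exact_two_sided_p(diffs):
    """Full 2^n sign-enumeration oracle for the signed-rank null."""
    diffs = np.asarray(diffs, float)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    observed = ranks[diffs > 0].sum()
    n = diffs.size
    total = ranks.sum()
    w_stats = [
        sum(r for r, pos in zip(ranks, signs) if pos)
        for signs in itertools.product([False, True], repeat=n)
    ]
    observed_dev = abs(observed - total / 2)
    extreme = sum(abs(w - total / 2) >= observed_dev - 1e-12 for w in w_stats)
    return extreme / 2**n


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        a = [0.8, 0.82, 0.85, 0.9, 0.95]
        b = [0.7, 0.71, 0.72, 0.73, 0.74]
        report = wilcoxon_compare(a, b)
        assert report.method == "exact"
        assert report.p == pytest.approx(0.0625)
        assert report.p == pytest.approx(_exact_two_sided_p(np.subtract(a, b)))
        assert not report.significant

    def test_matches_enumeration_on_mixed_signs(self, rng):
        for _ in range(10):
            d = rng.normal(size=8)
            a = 0.8 + d
            b = np.full(8, 0.8)
            report = wilcoxon_compare(a, b)
            assert report.p == pytest.approx(_exact_two_sided_p(d), rel=1e-9)

    def test_identical_lists_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            report = wilcoxon_compare([0.5, 0.6], [0.5, 0.6])
        assert report.p == 1.0
        assert report.method == "degenerate"

    def test_swap_symmetry(self, rng):
        a = rng.uniform(0.5, 1.0, size=12)
        b = rng.uniform(0.5, 1.0, size=12)
        fwd = wilcoxon_compare(a, b)
        rev = wilcoxon_compare(b, a)
        assert fwd.p == pytest.approx(rev.p)
        n = fwd.n_effective
        assert fwd.statistic + rev.statistic == pytest.approx(n * (n + 1) / 2)

    def test_normal_approx_branch_reports_z(self, rng):
        a = rng.uniform(0.5, 1.0, size=30)
        b = a + rng.normal(0.05, 0.05, size=30)
        report = wilcoxon_compare(list(a), list(b))
        assert report.method == "normal_approx"
        assert report.z is not None
        assert 0.0 <= report.p <= 1.0


class _SpyClassifier(ClassifierMixin, BaseEstimator):
    """Records the f0 values (subject codes) seen at fit time.

    The log is class-level because LOOCV clones the estimator per fold.
    """

    calls: list = []

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        _SpyClassifier.calls.append(set(X[:, 0].astype(int)))
        return self

    def predict(self, X):
        return np.zeros(len(X), dtype=int)


class TestLOOCV:
    def test_separable_classes_are_perfect(self):
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        subjects = [f"s{i // 2}" for i in range(8)]
        table = _table(labels, subjects)
        for clf in ("DT", "LDA"):
            assert loocv(table, clf, granularity="subject").accuracy == 1.0

    def test_subject_fold_count_equals_n_subjects(self):
        labels = [0, 0, 1, 1, 1, 0]
        subjects = ["a", "a", "b", "b", "c", "c"]
        result = loocv(_table(labels, subjects), "DT", granularity="subject")
        assert result.n_folds == 3

    def test_no_subject_straddles_train_and_test(self):
        labels = [0, 0, 1, 1, 0, 1]
        subjects = ["a", "a", "b", "b", "c", "c"]
        codes = [0, 0, 1, 1, 2, 2]  # f0 encodes the subject
        table = _table(labels, subjects, feature_values=codes)
        _SpyClassifier.calls = []
        loocv(table, _SpyClassifier(), granularity="subject")
        assert len(_SpyClassifier.calls) == 3
        all_codes = {0, 1, 2}
        for train_codes in _SpyClassifier.calls:
            assert len(all_codes - train_codes) == 1  # exactly one subject held out

    def test_majority_dummy_matches_counting_oracle(self, rng):
        """On a 51/39/21/18/12/3 label distribution a constant-majority
        predictor scores exactly the majority share 51/144."""
        counts = {0: 51, 1: 39, 2: 21, 3: 18, 4: 12, 5: 3}
        labels = np.concatenate([np.full(c, k) for k, c in counts.items()])
        subjects = [f"s{i}" for i in range(labels.size)]
        table = _table(labels, subjects, feature_values=rng.normal(size=labels.size))
        result = loocv(
            table, DummyClassifier(strategy="most_frequent"), granularity="segment"
        )
        assert result.accuracy == pytest.approx(51 / 144)
        assert result.n_folds == 144

    def test_confusion_trace_equals_accuracy(self, small_cohort):
        from spastimu import build_segment_table, feature_table, preprocess_recording

        portions = [preprocess_recording(r) for r in small_cohort]
        table = feature_table(build_segment_table(portions, "nonoverlap"), "FS1")
        result = loocv(table, "RF", granularity="subject", seed=0)
        assert result.confusion.sum() == result.true_labels.size
        assert result.confusion.trace() / result.confusion.sum() == pytest.approx(
            result.accuracy
        )

    def test_needs_two_units(self):
        table = _table([0, 1], ["a", "a"])
        with pytest.raises(ValueError, match="2 held-out units"):
            loocv(table, "DT", granularity="subject")

    def test_unknown_classifier(self):
        with pytest.raises(ValueError, match="classifier"):
            make_classifier("KNN")


class TestPerClassMetrics:
    def _result(self, true, pred):
        from spastimu.evaluate import CVResult
        from sklearn.metrics import confusion_matrix

        true = np.asarray(true)
        pred = np.asarray(pred)
        return CVResult(
            condition={},
            subject_ids=np.array([f"s{i}" for i in range(true.size)]),
            true_labels=true,
            predicted_labels=pred,
            accuracy=accuracy(true, pred),
            confusion=confusion_matrix(true, pred, labels=list(range(6))),
            n_folds=true.size,
            granularity="segment",
        )

    def test_perfect_predictions(self):
        metrics = per_class_metrics(self._result([0, 1, 2, 3], [0, 1, 2, 3]))
        for label in range(4):
            assert metrics.loc[label, "precision"] == 1.0
            assert metrics.loc[label, "recall"] == 1.0
            assert metrics.loc[label, "accuracy"] == 1.0

    def test_hand_computed_confusion(self):
        # confusion [[2,1],[0,3]] over classes 0 and 1
        metrics = per_class_metrics(self._result([0, 0, 0, 1, 1, 1], [0, 0, 1, 1, 1, 1]))
        assert metrics.loc[0, "precision"] == pytest.approx(1.0)
        assert metrics.loc[0, "recall"] == pytest.approx(2 / 3)
        assert metrics.loc[1, "precision"] == pytest.approx(0.75)
        assert metrics.loc[1, "recall"] == pytest.approx(1.0)

    def test_unpredicted_class_has_missing_precision(self):
        metrics = per_class_metrics(self._result([0, 0, 1], [0, 0, 0]))
        assert np.isnan(metrics.loc[1, "precision"])
        assert metrics.loc[1, "recall"] == 0.0
        assert np.isnan(metrics.loc[5, "recall"])  # absent from truth entirely


class TestConditionGrid:
    @pytest.fixture(scope="class")
    def tables(self, small_cohort):
        from spastimu import build_segment_table, feature_table, preprocess_recording
        from spastimu.segment import DATASET_BY_SCHEME

        portions = [preprocess_recording(r) for r in small_cohort]
        return {
            (DATASET_BY_SCHEME[scheme], fs): feature_table(
                build_segment_table(portions, scheme), fs
            )
            for scheme in ("nonoverlap", "overlap50")
            for fs in ("FS1", "FS2")
        }

    def test_grid_shape_and_aggregates(self, tables):
        grid = run_condition_grid(tables, classifiers=("DT", "LDA"), seed=0)
        assert len(grid.results) == 2 * 2 * 2
        assert set(grid.cell_medians) == {(d, f) for d in ("DS1", "DS2") for f in ("FS1", "FS2")}
        assert set(grid.feature_set_medians) == {"FS1", "FS2"}
        assert set(grid.dataset_medians) == {"DS1", "DS2"}
        assert set(grid.classifier_medians) == {"DT", "LDA"}
        # classifier medians pool the 4 dataset x feature-set accuracies
        for clf in ("DT", "LDA"):
            accs = [grid.results[(d, f, clf)].accuracy
                    for d in ("DS1", "DS2") for f in ("FS1", "FS2")]
            assert grid.classifier_medians[clf] == pytest.approx(np.median(accs))

    def test_comparisons_pair_over_other_factors(self, tables):
        grid = run_condition_grid(tables, classifiers=("DT", "LDA"), seed=0)
        for name in ("FS1_vs_FS2", "DS1_vs_DS2"):
            assert grid.comparisons[name].n_pairs == 4
            assert 0.0 <= grid.comparisons[name].p <= 1.0

    def test_every_cell_beats_majority_baseline(self, tables):
        """On an easy synthetic cohort every condition outperforms the
        constant-majority share (2/6 here)."""
        grid = run_condition_grid(tables, classifiers=("DT", "RF", "LDA"), seed=0)
        for cv in grid.results.values():
            assert cv.accuracy > 2 / 6

    def test_empty_classifier_list_rejected(self, tables):
        with pytest.raises(ValueError, match="empty"):
            run_condition_grid(tables, classifiers=())
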