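"""Classification and statistical comparison of MAS grading conditions.

Five classifier families — decision tree (DT), random forest (RF),
support vector machine (SVM), linear discriminant analysis (LDA) and
multilayer perceptron (MLP) — are evaluated under leave-one-out
cross-validation (LOOCV) on each combination of dataset (DS1/DS2) and
feature set (FS1/FS2). Accuracy is the fraction of held-out segments
whose predicted class matches the therapist's MAS label; conditions are
summarized by median accuracy and compared pairwise with the Wilcoxon
signed-rank test at alpha = 0.05.

The LOOCV unit defaults to the subject (leave-one-subject-out): every
segment of the held-out subject is predicted by a model trained on the
remaining subjects, so overlapping windows of one subject never straddle
the train/test split. Segment-granularity LOOCV is available behind a
flag. Features are z-scored with statistics fit on the training fold
only. All stochastic classifiers are seeded; hyperparameters are fixed
(RF: 100 trees; SVM: RBF kernel; MLP: one hidden layer of 64, no early
stopping; DT: unlimited depth; LDA: SVD solver, no shrinkage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import META_COLUMNS
from .simulate import MAS_LABELS

logger = logging.getLogger(__name__)

CLASSIFIERS = ("DT", "RF", "SVM", "LDA", "MLP")
GRANULARITIES = ("subject", "segment")


def make_classifier(name: str, seed: int = 0) -> Pipeline:
    """A freshly seeded scaler+classifier pipeline for one of the five families."""
    estimators = {
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "RF": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "SVM": lambda: SVC(kernel="rbf", decision_function_shape="ovr", random_state=seed),
        "LDA": lambda: LinearDiscriminantAnalysis(),
        "MLP": lambda: MLPClassifier(
            hidden_layer_sizes=(64,),
            max_iter=500,
            early_stopping=False,
            random_state=seed,
        ),
    }
    if name not in estimators:
        raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")
    return Pipeline([("scale", StandardScaler()), ("clf", estimators[name]())])


def accuracy(true_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Fraction of matching labels: (1/N) sum of I(g(x) = g_hat(x))."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("true and predicted label sequences must have equal length")
    if true_labels.size == 0:
        raise ValueError("cannot compute accuracy of zero predictions")
    return float(np.mean(true_labels == predicted_labels))


@dataclass
class CVResult:
    """Pooled LOOCV predictions for one (dataset, feature set, classifier)."""

    condition: dict[str, str]
    subject_ids: np.ndarray
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    accuracy: float
    confusion: np.ndarray
    n_folds: int
    granularity: str


def loocv(
    table: pd.DataFrame,
    classifier: str | BaseEstimator = "RF",
    granularity: str = "subject",
    seed: int = 0,
    condition: dict[str, str] | None = None,
) -> CVResult:
    """Leave-one-out cross-validation over a feature matrix.

    ``granularity="subject"`` holds out all segments of one subject per
    fold; ``"segment"`` holds out a single row per fold (note that with
    50%-overlapping windows this leaks near-duplicate samples into the
    training set). A fold whose training set lacks a class — unavoidable
    for singleton classes — is permitted and logged.
    """
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}")
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    if not feature_cols or table.empty:
        raise ValueError("feature table is empty")
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["mas_label"].to_numpy(dtype=int)
    subjects = table["subject_id"].to_numpy()
    all_classes = set(np.unique(y))
    if granularity == "subject":
        units = [subjects == s for s in sorted(set(subjects))]
    else:
        units = [np.arange(len(y)) == i for i in range(len(y))]
    if len(units) < 2:
        raise ValueError("LOOCV needs at least 2 held-out units")

    predictions = np.empty_like(y)
    for test_mask in units:
        train_mask = ~test_mask
        train_classes = set(np.unique(y[train_mask]))
        if train_classes != all_classes:
            logger.info(
                "fold trains without class(es) %s (singleton in cohort)",
                sorted(all_classes - train_classes),
            )
        model = (
            make_classifier(classifier, seed)
            if isinstance(classifier, str)
            else clone(classifier)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[train_mask], y[train_mask])
            predictions[test_mask] = model.predict(X[test_mask])

    return CVResult(
        condition=dict(condition or {}),
        subject_ids=subjects,
        true_labels=y,
        predicted_labels=predictions,
        accuracy=accuracy(y, predictions),
        confusion=confusion_matrix(y, predictions, labels=list(MAS_LABELS)),
        n_folds=len(units),
        granularity=granularity,
    )


def per_class_metrics(result: CVResult) -> pd.DataFrame:
    """Per-class precision, recall and their mean ("accuracy" column).

    Classes with no predicted instances have undefined precision and
    classes absent from the truth have undefined recall; both are
    reported as NaN, never as 0.
    """
    conf = result.confusion.astype(float)
    tp = np.diag(conf)
    predicted = conf.sum(axis=0)
    actual = conf.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, np.nan)
        recall = np.where(actual > 0, tp / actual, np.nan)
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "accuracy": (precision + recall) / 2.0,
        },
        index=pd.Index(list(MAS_LABELS), name="mas_label"),
    )


def median_accuracy(accuracies: list[float]) -> float:
    """Standard median (mean of the middle two for even n)."""
    if len(accuracies) == 0:
        raise ValueError("median of an empty accuracy list")
    return float(np.median(accuracies))


@dataclass
class ComparisonReport:
    """Paired Wilcoxon signed-rank comparison of two accuracy lists."""

    n_pairs: int
    n_effective: int
    statistic: float  # W+: rank sum of positive differences
    z: float | None  # normal-approximation branch only
    p: float
    alpha: float
    significant: bool
    method: str


def wilcoxon_compare(
    paired_a: list[float], paired_b: list[float], alpha: float = 0.05
) -> ComparisonReport:
    """Two-sided Wilcoxon signed-rank test on paired accuracies.

    Zero differences are dropped before ranking. The exact null
    distribution is used when the effective n is at most 25 and the
    absolute differences are tie-free; otherwise the normal
    approximation with tie correction is used and Z is reported. If all
    differences are zero the comparison is degenerate and p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired accuracy lists must have equal length")
    d = a - b
    nz = d[d != 0]
    n_eff = nz.size
    if n_eff == 0:
        warnings.warn("all paired differences are zero; comparison is degenerate", RuntimeWarning)
        return ComparisonReport(
            n_pairs=d.size, n_effective=0, statistic=float("nan"), z=None,
            p=1.0, alpha=alpha, significant=False, method="degenerate",
        )
    ranks = scipy.stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    tie_free = np.unique(np.abs(nz)).size == n_eff
    if n_eff <= 25 and tie_free:
        res = scipy.stats.wilcoxon(nz, alternative="two-sided", method="exact")
        z = None
        method = "exact"
    else:
        res = scipy.stats.wilcoxon(
            nz, alternative="two-sided", method="approx", correction=False
        )
        z = float(res.zstatistic)
        method = "normal_approx"
    p = float(res.pvalue)
    return ComparisonReport(
        n_pairs=d.size, n_effective=n_eff, statistic=w_pos, z=z,
        p=p, alpha=alpha, significant=bool(p < alpha), method=method,
    )


@dataclass
class GridResult:
    """All condition-wise CV results plus the summary aggregates."""

    results: dict[tuple[str, str, str], CVResult]
    cell_medians: dict[tuple[str, str], float] = field(default_factory=dict)
    feature_set_medians: dict[str, float] = field(default_factory=dict)
    dataset_medians: dict[str, float] = field(default_factory=dict)
    classifier_medians: dict[str, float] = field(default_factory=dict)
    comparisons: dict[str, ComparisonReport] = field(default_factory=dict)


def run_condition_grid(
    tables: dict[tuple[str, str], pd.DataFrame],
    granularity: str = "subject",
    seed: int = 0,
    classifiers: tuple[str, ...] = CLASSIFIERS,
) -> GridResult:
    """Evaluate every (dataset, feature set, classifier) condition.

    ``tables`` maps (dataset, feature_set) — e.g. ("DS2", "FS1") — to a
    feature matrix. With both datasets and both feature sets present the
    grid has 2 x 2 x len(classifiers) conditions. Aggregates mirror the
    reporting conventions: median over classifiers per cell, per feature
    set pooled over datasets, per dataset pooled over feature sets, and
    per classifier pooled over everything; the FS1-vs-FS2 and DS1-vs-DS2
    comparisons pair accuracies over the non-compared factors.
    """
    if not tables:
        raise ValueError("no feature tables supplied")
    if not classifiers:
        raise ValueError("classifier list is empty")
    datasets = sorted({ds for ds, _ in tables})
    feature_sets = sorted({fs for _, fs in tables})
    results: dict[tuple[str, str, str], CVResult] = {}
    for (ds, fs), table in sorted(tables.items()):
        for clf in classifiers:
            condition = {"dataset": ds, "feature_set": fs, "classifier": clf}
            results[(ds, fs, clf)] = loocv(
                table, clf, granularity=granularity, seed=seed, condition=condition
            )
            logger.info(
                "%s/%s/%s accuracy=%.3f", ds, fs, clf, results[(ds, fs, clf)].accuracy
            )

    def _median(keys: list[tuple[str, str, str]]) -> float:
        return median_accuracy([results[k].accuracy for k in keys])

    grid = GridResult(results=results)
    for ds in datasets:
        for fs in feature_sets:
            if (ds, fs) in tables:
                grid.cell_medians[(ds, fs)] = _median(
                    [(ds, fs, c) for c in classifiers]
                )
    for fs in feature_sets:
        keys = [(ds, fs, c) for ds in datasets for c in classifiers if (ds, fs) in tables]
        grid.feature_set_medians[fs] = _median(keys)
    for ds in datasets:
        keys = [(ds, fs, c) for fs in feature_sets for c in classifiers if (ds, fs) in tables]
        grid.dataset_medians[ds] = _median(keys)
    for clf in classifiers:
        keys = [(ds, fs, clf) for ds in datasets for fs in feature_sets if (ds, fs) in tables]
        grid.classifier_medians[clf] = _median(keys)

    if {"FS1", "FS2"} <= set(feature_sets):
        pairs = [
            (ds, c)
            for ds in datasets
            for c in classifiers
            if (ds, "FS1") in tables and (ds, "FS2") in tables
        ]
        grid.comparisons["FS1_vs_FS2"] = wilcoxon_compare(
            [results[(ds, "FS1", c)].accuracy for ds, c in pairs],
            [results[(ds, "FS2", c)].accuracy for ds, c in pairs],
        )
    if {"DS1", "DS2"} <= set(datasets):
        pairs = [
            (fs, c)
            for fs in feature_sets
            for c in classifiers
            if ("DS1", fs) in tables and ("DS2", fs) in tables
        ]
        grid.comparisons["DS1_vs_DS2"] = wilcoxon_compare(
            [results[("DS1", fs, c)].accuracy for fs, c in pairs],
            [results[("DS2", fs, c)].accuracy for fs, c in pairs],
        )
    return grid
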