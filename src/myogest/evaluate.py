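"""Repeated-trial evaluation and statistical comparison of classifiers.

The protocol: each classifier is run for a number of independent trials
(30 by default); each trial draws a fresh stratified 80/20 split, re-seeds
the classifier, and records train and test accuracy.  Classifiers are then
compared pairwise with two-sided Welch t-tests on the test accuracies, and
the raw p-values are adjusted with the step-down Holm procedure, which
controls the family-wise error rate over the three pairs.

Welch's unequal-variance variant is used because accuracy spreads differ
substantially between classifiers (tree accuracies are far noisier than
SVM accuracies), making the pooled-variance test unsafe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .classify import ClassifierSpec, TrainedClassifier, accuracy, predict, split_dataset, train
from .synth import GestureLabel

__all__ = [
    "TrialResultSet",
    "ConfusionMatrix",
    "PairwiseTest",
    "ComparisonReport",
    "run_trials",
    "confusion",
    "welch_t",
    "holm_adjust",
    "compare",
]

_N_CLASSES = len(GestureLabel)


@dataclass
class TrialResultSet:
    """Per-trial train/test accuracies (%) for one classifier, plus the
    test-set confusion counts accumulated over all trials."""

    kind: str
    train_accuracies: np.ndarray
    test_accuracies: np.ndarray
    confusion_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_accuracies, dtype=float)
        te = np.asarray(self.test_accuracies, dtype=float)
        if tr.shape != te.shape:
            raise ValueError("train and test accuracy vectors must have equal length")
        for v in (tr, te):
            if v.size and (v.min() < 0 or v.max() > 100):
                raise ValueError("accuracies must lie in [0, 100]")
        self.train_accuracies = tr
        self.test_accuracies = te

    @property
    def n_trials(self) -> int:
        return self.test_accuracies.size


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized (true-class) confusion percentages.

    Rows and columns follow the gesture order (close, open, wave_in,
    wave_out); each row sums to 100%.
    """

    rows_percent: np.ndarray
    overall_accuracy: float

    def __post_init__(self) -> None:
        m = np.asarray(self.rows_percent, dtype=float)
        if m.shape != (_N_CLASSES, _N_CLASSES):
            raise ValueError(f"confusion matrix must be {_N_CLASSES}x{_N_CLASSES}")
        if np.any(m < 0):
            raise ValueError("confusion entries must be non-negative")
        if not np.allclose(m.sum(axis=1), 100.0, atol=0.01):
            raise ValueError("each confusion row must sum to 100%")
        object.__setattr__(self, "rows_percent", m)

    def to_frame(self) -> pd.DataFrame:
        names = [g.name.lower() for g in GestureLabel]
        return pd.DataFrame(self.rows_percent, index=names, columns=names)


@dataclass(frozen=True)
class PairwiseTest:
    """One pairwise classifier comparison on test accuracies."""

    pair: tuple[str, str]
    t_statistic: float
    p_raw: float
    p_holm: float


@dataclass
class ComparisonReport:
    """Summary of the repeated-trial comparison.

    ``summary`` holds mean and SD of train/test accuracy per classifier;
    ``pairwise`` the Welch tests with Holm-adjusted p-values;
    ``confusions`` the aggregated test confusion matrix per classifier;
    ``best_classifier`` the kind with the highest mean test accuracy.
    """

    summary: pd.DataFrame
    pairwise: list[PairwiseTest]
    best_classifier: str
    confusions: dict[str, ConfusionMatrix] = field(default_factory=dict)
    alpha: float = 0.05


def _confusion_counts(model: TrainedClassifier, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    pred = np.asarray(predict(model, np.asarray(X, dtype=float)))
    counts = np.zeros((_N_CLASSES, _N_CLASSES), dtype=np.int64)
    for t, p in zip(np.asarray(y, dtype=int), pred.astype(int)):
        counts[t, p] += 1
    return counts


def run_trials(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_trials: int = 30,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> TrialResultSet:
    """Run the repeated random-split protocol for one classifier.

    Both the split and the classifier initialization are re-seeded each
    trial from sub-seeds spawned deterministically off ``seed``, so the
    whole result set is reproducible while trials stay independent.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    children = np.random.SeedSequence(seed).spawn(n_trials)
    train_acc = np.empty(n_trials)
    test_acc = np.empty(n_trials)
    counts = np.zeros((_N_CLASSES, _N_CLASSES), dtype=np.int64)
    for i, child in enumerate(children):
        split_seed, clf_seed = (int(s) for s in child.generate_state(2) & 0x7FFFFFFF)
        split = split_dataset(y, test_fraction=test_fraction, seed=split_seed)
        trial_spec = replace(spec, seed=clf_seed)
        model = train(trial_spec, X[split.train_idx], y[split.train_idx])
        train_acc[i] = accuracy(model, X[split.train_idx], y[split.train_idx])
        test_acc[i] = accuracy(model, X[split.test_idx], y[split.test_idx])
        counts += _confusion_counts(model, X[split.test_idx], y[split.test_idx])
    return TrialResultSet(
        kind=spec.kind,
        train_accuracies=train_acc,
        test_accuracies=test_acc,
        confusion_counts=counts,
    )


def _normalize_counts(counts: np.ndarray) -> ConfusionMatrix:
    counts = np.asarray(counts, dtype=float)
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every true class must appear at least once")
    percent = 100.0 * counts / row_sums[:, None]
    overall = 100.0 * float(np.trace(counts) / counts.sum())
    return ConfusionMatrix(rows_percent=percent, overall_accuracy=overall)


def confusion(model: TrainedClassifier, X: np.ndarray, y: np.ndarray) -> ConfusionMatrix:
    """Row-normalized confusion matrix of ``model`` on a labeled set.

    Entry (i, j) is the percentage of true-class-i samples predicted as
    class j; all four gestures must be present in ``y``.
    """
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {int(g) for g in GestureLabel}:
        raise ValueError("all four gesture classes must be present")
    return _normalize_counts(_confusion_counts(model, X, y))


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Returns ``(t, p)``.  The degenerate case of two identical constant
    samples is defined as no evidence of difference: ``(0.0, 1.0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs at least 2 observations per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = _stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment, returned in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def compare(results: list[TrialResultSet], alpha: float = 0.05) -> ComparisonReport:
    """Build the comparison report from per-classifier trial results.

    Requires at least two result sets with equal trial counts.  All
    pairwise Welch tests on test accuracies form the Holm family.
    """
    if len(results) < 2:
        raise ValueError("compare needs at least 2 result sets")
    n = {r.n_trials for r in results}
    if len(n) != 1:
        raise ValueError("all result sets must have the same number of trials")
    kinds = [r.kind for r in results]
    if len(set(kinds)) != len(kinds):
        raise ValueError("duplicate classifier kinds in results")

    summary = pd.DataFrame(
        {
            "train_mean": [r.train_accuracies.mean() for r in results],
            "train_sd": [r.train_accuracies.std(ddof=1) for r in results],
            "test_mean": [r.test_accuracies.mean() for r in results],
            "test_sd": [r.test_accuracies.std(ddof=1) for r in results],
        },
        index=pd.Index(kinds, name="classifier"),
    )

    pairs = list(itertools.combinations(range(len(results)), 2))
    raw = np.empty(len(pairs))
    t_stats = np.empty(len(pairs))
    for i, (j, k) in enumerate(pairs):
        t_stats[i], raw[i] = welch_t(results[j].test_accuracies, results[k].test_accuracies)
    adjusted = holm_adjust(raw)
    pairwise = [
        PairwiseTest(
            pair=(kinds[j], kinds[k]),
            t_statistic=float(t_stats[i]),
            p_raw=float(raw[i]),
            p_holm=float(adjusted[i]),
        )
        for i, (j, k) in enumerate(pairs)
    ]

    confusions = {
        r.kind: _normalize_counts(r.confusion_counts)
        for r in results
        if r.confusion_counts is not None and r.confusion_counts.sum() > 0
    }
    best = summary["test_mean"].idxmax()
    return ComparisonReport(
        summary=summary,
        pairwise=pairwise,
        best_classifier=str(best),
        confusions=confusions,
        alpha=alpha,
    )
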