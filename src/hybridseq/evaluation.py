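"""Confusion matrices, classification metrics, curves, splits and the
two-classifier significance tests.

Metrics follow the standard binary definitions:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = recall = TP / (TP + FN)
    F1          = 2 TP / (2 TP + FP + FN)

Two classifiers evaluated on the same test set of size n are compared
with a pooled two-proportion Z statistic and a 2×2 chi-squared test of
(classifier × correct/incorrect) counts without continuity correction;
the 95% thresholds are the two-sided normal critical value (1.96) and
the df=1 chi-squared critical value (3.841).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    sensitivity: float
    f1: float


@dataclass(frozen=True)
class ComparisonTest:
    z_statistic: float
    chi2_statistic: float
    p_value: float
    significant_95: bool


@dataclass(frozen=True)
class SplitPlan:
    train: tuple[int, ...] | None
    test: tuple[int, ...] | None
    folds: tuple[tuple[int, ...], ...] | None
    seed: int


def confusion(
    y_true: Sequence, y_pred: Sequence, positive_class
) -> ConfusionMatrix:
    """Brute-force TP/FP/TN/FN counts after binarizing on the positive class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred differ in length")
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 denominator, reporting 0")
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        precision=precision,
        recall=recall,
        sensitivity=recall,
        f1=_safe_div(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1"),
    )


def roc_curve(
    y_true: Sequence, scores: Sequence, positive_class=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(FPR, TPR, thresholds, trapezoidal AUC) from a threshold sweep."""
    yt = np.asarray(y_true)
    if len(np.unique(yt)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _skm.roc_curve(yt, np.asarray(scores, dtype=float),
                                   pos_label=positive_class)
    return fpr, tpr, thr, float(_skm.auc(fpr, tpr))


def pr_curve(
    y_true: Sequence, scores: Sequence, positive_class=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(recall, precision, thresholds) over the score sweep."""
    yt = np.asarray(y_true)
    if len(np.unique(yt)) < 2:
        raise ValueError("precision-recall requires both classes present")
    precision, recall, thr = _skm.precision_recall_curve(
        yt, np.asarray(scores, dtype=float), pos_label=positive_class
    )
    return recall, precision, thr


def z_critical(confidence: float = 0.95) -> float:
    """Two-sided normal critical value (1.96 at 95%)."""
    return float(stats.norm.ppf(0.5 + confidence / 2))


def chi2_critical(alpha: float = 0.05, df: int = 1) -> float:
    """Upper chi-squared critical value (3.841 at alpha=0.05, df=1)."""
    return float(stats.chi2.ppf(1 - alpha, df))


def z_test(acc_a: float, acc_b: float, n: int) -> ComparisonTest:
    """Pooled two-proportion Z test of two accuracies on n test samples.

    Z = (a - b) / sqrt(2 p̄ (1 - p̄) / n) with p̄ = (a + b) / 2.
    """
    if not (0 <= acc_a <= 1 and 0 <= acc_b <= 1):
        raise ValueError("accuracies must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    pbar = (acc_a + acc_b) / 2
    if pbar in (0.0, 1.0):
        z = 0.0 if acc_a == acc_b else float(np.sign(acc_a - acc_b) * np.inf)
    else:
        z = (acc_a - acc_b) / np.sqrt(2 * pbar * (1 - pbar) / n)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return ComparisonTest(
        z_statistic=float(z),
        chi2_statistic=float("nan"),
        p_value=p,
        significant_95=bool(abs(z) > z_critical(0.95)),
    )


def chi2_test(correct_a: int, correct_b: int, n: int) -> ComparisonTest:
    """2×2 (classifier × correct/incorrect) chi-squared test, df=1, no Yates."""
    if not (0 <= correct_a <= n and 0 <= correct_b <= n):
        raise ValueError("correct counts must lie in [0, n]")
    table = np.array(
        [[correct_a, n - correct_a], [correct_b, n - correct_b]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0):
        # both classifiers all-correct or all-incorrect: no association
        chi2 = 0.0
        p = 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonTest(
        z_statistic=float("nan"),
        chi2_statistic=float(chi2),
        p_value=float(p),
        significant_95=bool(chi2 > chi2_critical(0.05, 1)),
    )


def compare_accuracies(correct_a: int, correct_b: int, n: int) -> ComparisonTest:
    """Both tests for one classifier pair on the same n-sample test set."""
    zres = z_test(correct_a / n, correct_b / n, n)
    cres = chi2_test(correct_a, correct_b, n)
    return ComparisonTest(
        z_statistic=zres.z_statistic,
        chi2_statistic=cres.chi2_statistic,
        p_value=zres.p_value,
        significant_95=zres.significant_95,
    )


def holdout_split(n: int, train_fraction: float = 0.6, seed: int = 0) -> SplitPlan:
    """Single random unstratified partition; floor(train_fraction · n) to train."""
    if n < 2:
        raise ValueError("need at least two samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return SplitPlan(
        train=tuple(int(i) for i in order[:n_train]),
        test=tuple(int(i) for i in order[n_train:]),
        folds=None,
        seed=seed,
    )


def kfold_split(n: int, k: int = 5, seed: int = 0) -> SplitPlan:
    """k shuffled folds with sizes differing by at most one."""
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = tuple(
        tuple(int(i) for i in fold) for fold in np.array_split(order, k)
    )
    return SplitPlan(train=None, test=None, folds=folds, seed=seed)
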