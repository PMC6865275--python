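"""Statistical evaluation of tissue classifiers.

Performance is assessed one-vs-rest per class with accuracy, recall,
precision, specificity and F1, plus an unweighted mean row over the
four classes.  95% confidence intervals come from bootstrapping the
(label, prediction) pairs (percentile method, B = 2000 by default).
Two classifiers evaluated on the same tissues are compared with the
two-tailed McNemar-Bowker symmetry test on their paired K x K
disagreement table.  Per-class ROC curves/AUCs are computed one-vs-rest
from the predicted class probabilities.

Zero-denominator metrics (e.g. recall for a class absent from the
sample) are reported as 0 with an ``undefined`` flag rather than NaN,
keeping mean rows computable; the flag is preserved in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classes import CLASS_ORDER

__all__ = [
    "METRIC_NAMES",
    "confusion_matrix",
    "one_vs_rest_metrics",
    "mean_metrics",
    "bootstrap_ci",
    "metrics_report",
    "mcnemar_bowker",
    "roc_auc_one_vs_rest",
    "MetricsReport",
]

METRIC_NAMES = ("accuracy", "recall", "precision", "specificity", "f1")


def confusion_matrix(y_true, y_pred, classes=CLASS_ORDER) -> np.ndarray:
    """K x K counts; rows are the reference standard, columns predictions."""
    return _sk_confusion(list(y_true), list(y_pred), labels=list(classes))


def _counts_from_cm(cm: np.ndarray, idx: int):
    cm = np.asarray(cm)
    tp = cm[idx, idx]
    fn = cm[idx].sum() - tp
    fp = cm[:, idx].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return int(tp), int(fp), int(fn), int(tn)


def one_vs_rest_metrics(cm: np.ndarray, cls: str | int,
                        classes=CLASS_ORDER) -> dict[str, float]:
    """Accuracy, recall, precision, specificity and F1 for one class.

    The K-class matrix is collapsed to class-vs-rest counts.  Metrics
    with a zero denominator are returned as 0 and listed under the
    ``undefined`` key.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any() or cm.sum() == 0:
        raise ValueError("confusion matrix must be square, nonnegative, nonempty")
    idx = cls if isinstance(cls, int) else list(classes).index(cls)
    tp, fp, fn, tn = _counts_from_cm(cm, idx)
    n = tp + fp + fn + tn
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    out = dict(
        accuracy=(tp + tn) / n,
        recall=recall,
        precision=precision,
        specificity=ratio(tn, tn + fp, "specificity"),
        f1=ratio(2 * precision * recall, precision + recall, "f1"),
    )
    out["undefined"] = tuple(undefined)
    return out


def mean_metrics(per_class: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted arithmetic mean of each metric over the classes."""
    return {m: float(np.mean([per_class[c][m] for c in per_class])) for m in METRIC_NAMES}


def bootstrap_ci(labels, predictions, metric, B: int = 2000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap interval for a paired classification metric.

    ``metric`` is a callable ``metric(y_true, y_pred) -> float``.  The
    point estimate is the plug-in value on the original sample;
    resampling the (label, prediction) pairs with replacement B times
    gives the percentile interval.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape or labels.size < 2:
        raise ValueError("need >= 2 paired labels/predictions")
    if B < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    point = float(metric(labels, predictions))
    vals = np.empty(B)
    n = labels.size
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        vals[b] = metric(labels[idx], predictions[idx])
    lo, hi = np.percentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return point, float(lo), float(hi)


@dataclass
class MetricsReport:
    """Per-class and mean metrics, each with a bootstrap CI."""

    table: pd.DataFrame  # columns: class, metric, point, ci_low, ci_high
    undefined: dict[str, tuple] = field(default_factory=dict)

    def point(self, cls: str, metric: str) -> float:
        row = self.table[(self.table["class"] == cls) & (self.table["metric"] == metric)]
        return float(row["point"].iloc[0])


def _metric_fn(metric: str, cls: str, classes):
    def fn(y_true, y_pred):
        cm = confusion_matrix(y_true, y_pred, classes)
        return one_vs_rest_metrics(cm, cls, classes)[metric]
    return fn


def metrics_report(labels, predictions, classes=CLASS_ORDER, B: int = 2000,
                   level: float = 0.95, seed: int = 0) -> MetricsReport:
    """Full report: five metrics x (each class + unweighted mean), with CIs."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    cm = confusion_matrix(labels, predictions, classes)
    per_class = {c: one_vs_rest_metrics(cm, c, classes) for c in classes}
    rows = []
    undefined = {c: per_class[c]["undefined"] for c in classes if per_class[c]["undefined"]}
    for metric in METRIC_NAMES:
        for c in classes:
            pt, lo, hi = bootstrap_ci(labels, predictions, _metric_fn(metric, c, classes),
                                      B=B, level=level, seed=seed)
            rows.append(dict(cls=c, metric=metric, point=pt, ci_low=lo, ci_high=hi))

        def mean_fn(y_true, y_pred, m=metric):
            cmx = confusion_matrix(y_true, y_pred, classes)
            return float(np.mean([one_vs_rest_metrics(cmx, c, classes)[m] for c in classes]))

        pt, lo, hi = bootstrap_ci(labels, predictions, mean_fn, B=B, level=level, seed=seed)
        rows.append(dict(cls="mean", metric=metric, point=pt, ci_low=lo, ci_high=hi))
    table = pd.DataFrame(rows).rename(columns={"cls": "class"})
    return MetricsReport(table=table, undefined=undefined)


def mcnemar_bowker(pred_a, pred_b, classes=CLASS_ORDER) -> tuple[float, int, float]:
    """Two-tailed McNemar-Bowker symmetry test on paired predictions.

    Builds the K x K table of (classifier-A class, classifier-B class)
    pairs over the same samples and tests its symmetry:
    ``X2 = sum_{i<j} (n_ij - n_ji)^2 / (n_ij + n_ji)`` over pairs with
    ``n_ij + n_ji > 0``; the degrees of freedom count those pairs.
    Returns ``(statistic, df, p)``; a table with no off-diagonal
    disagreement gives (0, 0, 1).
    """
    pred_a = list(pred_a)
    pred_b = list(pred_b)
    if len(pred_a) != len(pred_b) or not pred_a:
        raise ValueError("need paired, nonempty prediction vectors")
    table = confusion_matrix(pred_a, pred_b, classes)
    stat, df = 0.0, 0
    k = table.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            s = table[i, j] + table[j, i]
            if s > 0:
                stat += (table[i, j] - table[j, i]) ** 2 / s
                df += 1
    if df == 0:
        return 0.0, 0, 1.0
    return float(stat), df, float(sps.chi2.sf(stat, df))


def roc_auc_one_vs_rest(labels, probabilities, cls: str, classes=CLASS_ORDER):
    """One-vs-rest ROC curve and trapezoidal AUC for one class.

    ``probabilities`` is (n, K) in the order of ``classes``.  With only
    one class present in the labels the AUC is undefined: the curve is
    returned with ``auc = nan`` and a warning.
    """
    labels = np.asarray(labels)
    probs = np.asarray(probabilities, dtype=float)
    idx = list(classes).index(cls)
    y = (labels == cls).astype(int)
    if y.min() == y.max():
        warnings.warn(f"AUC undefined: only one class present for {cls!r}", stacklevel=2)
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), float("nan")
    fpr, tpr, _ = _sk_roc_curve(y, probs[:, idx])
    return fpr, tpr, float(_sk_auc(fpr, tpr))
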