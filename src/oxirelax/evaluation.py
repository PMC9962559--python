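"""Per-class precision/recall/F1 and repetition-aggregated reporting.

One training session yields a confusion matrix on its test set; the
experiment driver repeats training with fresh initializations and
splits, and the aggregate report gives each metric's median and
interquartile range across repetitions, plus the total number of
individual test predictions (repetitions x test-set size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import InvalidInputError
from .labels import CLASS_ORDER


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = true class, columns = predicted class, order = ``labels``."""

    counts: np.ndarray
    labels: tuple = CLASS_ORDER

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if c.shape != (k, k) or np.any(c < 0):
            raise InvalidInputError("counts must be a non-negative square matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total


def confusion(true_labels, predicted_labels, labels=CLASS_ORDER) -> ConfusionMatrix:
    """Tally a confusion matrix from label sequences (strings or indices)."""
    t = [_as_label(x, labels) for x in true_labels]
    p = [_as_label(x, labels) for x in predicted_labels]
    if len(t) != len(p) or len(t) == 0:
        raise InvalidInputError("label sequences must have equal nonzero length")
    counts = _sk_confusion(t, p, labels=list(labels))
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def _as_label(x, labels):
    if isinstance(x, str):
        if x not in labels:
            raise InvalidInputError(f"unknown label {x!r}")
        return x
    i = int(x)
    if not 0 <= i < len(labels):
        raise InvalidInputError(f"label index {i} out of range")
    return labels[i]


def class_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class precision, recall, F1 and support from a confusion matrix.

    A class never predicted gets precision 0 (with a warning); a class
    with zero support gets recall 0 (with a warning).  F1 is the harmonic
    mean, 0 when precision + recall == 0.
    """
    c = cm.counts.astype(float)
    tp = np.diag(c)
    pred_pos = c.sum(axis=0)
    support = c.sum(axis=1)
    out = {}
    for i, label in enumerate(cm.labels):
        if pred_pos[i] == 0:
            warnings.warn(f"class {label!r} was never predicted; precision set to 0",
                          stacklevel=2)
            precision = 0.0
        else:
            precision = tp[i] / pred_pos[i]
        if support[i] == 0:
            warnings.warn(f"class {label!r} has zero support; recall set to 0", stacklevel=2)
            recall = 0.0
        else:
            recall = tp[i] / support[i]
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        out[label] = {"precision": float(precision), "recall": float(recall),
                      "f1": float(f1), "support": int(support[i])}
    return out


def weighted_f1(per_class: dict) -> float:
    """Support-weighted mean of per-class F1 scores."""
    supports = np.array([m["support"] for m in per_class.values()], dtype=float)
    if supports.sum() == 0:
        raise InvalidInputError("total support is zero")
    f1s = np.array([m["f1"] for m in per_class.values()])
    return float(np.sum(f1s * supports) / supports.sum())


_METRICS = ("precision", "recall", "f1")


@dataclass(frozen=True)
class EvalReport:
    """Evaluation of one session, or the aggregate of several.

    ``aggregate`` (present when ``n_repetitions > 1``) maps class ->
    metric -> {median, iqr}; the ``Overall`` pseudo-class carries both
    the pooled micro metrics (accuracy over all predictions) and the
    support-weighted macro metrics, labeled distinctly.
    """

    per_class: dict
    accuracy: float
    weighted_avg_f1: float
    n_repetitions: int = 1
    total_tests: int = 0
    aggregate: dict | None = None

    def __post_init__(self):
        for m in self.per_class.values():
            for key in _METRICS:
                if not 0 <= m[key] <= 1:
                    raise InvalidInputError(f"{key} outside [0, 1]")

    @property
    def support_sum(self) -> int:
        return int(sum(m["support"] for m in self.per_class.values()))

    def to_dict(self) -> dict:
        out = {"per_class": self.per_class, "accuracy": self.accuracy,
               "weighted_avg_f1": self.weighted_avg_f1,
               "n_repetitions": self.n_repetitions, "total_tests": self.total_tests}
        if self.aggregate is not None:
            out["aggregate"] = self.aggregate
        return out


def evaluate(true_labels, predicted_labels, labels=CLASS_ORDER) -> EvalReport:
    """Single-session report straight from label sequences."""
    cm = confusion(true_labels, predicted_labels, labels)
    per_class = class_metrics(cm)
    return EvalReport(per_class=per_class, accuracy=cm.accuracy,
                      weighted_avg_f1=weighted_f1(per_class),
                      n_repetitions=1, total_tests=cm.total)


def _median_iqr(values) -> dict:
    v = np.asarray(values, dtype=float)
    q25, q50, q75 = np.percentile(v, [25, 50, 75])  # linear-interpolation quantiles
    return {"median": float(q50), "iqr": [float(q25), float(q75)]}


def aggregate_repetitions(reports: list[EvalReport]) -> EvalReport:
    """Median and [25th, 75th] percentile of each metric across repetitions."""
    if not reports:
        raise InvalidInputError("need at least one report")
    first = reports[0]
    labels = tuple(first.per_class.keys())
    for r in reports[1:]:
        if tuple(r.per_class.keys()) != labels:
            raise InvalidInputError("reports have inconsistent class sets")
        if any(r.per_class[c]["support"] != first.per_class[c]["support"] for c in labels):
            raise InvalidInputError("reports have inconsistent supports")
    n_rep = len(reports)
    aggregate = {}
    for c in labels:
        aggregate[c] = {m: _median_iqr([r.per_class[c][m] for r in reports])
                        for m in _METRICS}
        aggregate[c]["support"] = first.per_class[c]["support"]
    aggregate["Overall"] = {
        "micro_accuracy": _median_iqr([r.accuracy for r in reports]),
        "weighted_f1": _median_iqr([r.weighted_avg_f1 for r in reports]),
        "weighted_precision": _median_iqr([
            sum(r.per_class[c]["precision"] * r.per_class[c]["support"] for c in labels)
            / r.support_sum for r in reports]),
        "weighted_recall": _median_iqr([
            sum(r.per_class[c]["recall"] * r.per_class[c]["support"] for c in labels)
            / r.support_sum for r in reports]),
    }
    # representative per-class point values: the across-repetition medians
    per_class = {c: {m: aggregate[c][m]["median"] for m in _METRICS}
                 | {"support": first.per_class[c]["support"]} for c in labels}
    return EvalReport(
        per_class=per_class,
        accuracy=aggregate["Overall"]["micro_accuracy"]["median"],
        weighted_avg_f1=aggregate["Overall"]["weighted_f1"]["median"],
        n_repetitions=n_rep,
        total_tests=n_rep * first.support_sum,
        aggregate=aggregate,
    )


def report_table(agg: EvalReport) -> pd.DataFrame:
    """Aggregate report as a table: one column per class plus Overall.

    Rows: repetitions, support, total tests, then median [IQR] strings
    for precision, recall and F1.
    """
    if agg.aggregate is None:
        raise InvalidInputError("report_table needs an aggregated report")
    labels = [c for c in agg.per_class.keys()]
    cols = {}

    def fmt(stat, pct=False):
        if pct:
            return (f"{100 * stat['median']:.0f}% "
                    f"[{100 * stat['iqr'][0]:.0f}%, {100 * stat['iqr'][1]:.0f}%]")
        return f"{stat['median']:.2f} [{stat['iqr'][0]:.2f}, {stat['iqr'][1]:.2f}]"

    for c in labels:
        a = agg.aggregate[c]
        cols[c] = [agg.n_repetitions, a["support"], agg.n_repetitions * a["support"],
                   fmt(a["precision"], pct=True), fmt(a["recall"], pct=True), fmt(a["f1"])]
    ov = agg.aggregate["Overall"]
    cols["Overall"] = [agg.n_repetitions, agg.support_sum, agg.total_tests,
                       fmt(ov["weighted_precision"], pct=True),
                       fmt(ov["weighted_recall"], pct=True), fmt(ov["weighted_f1"])]
    index = ["Number of repetitions", "Support", "Total number of tests",
             "Precision (median, [IQR])", "Recall (median, [IQR])",
             "F1-score (median, [IQR])"]
    return pd.DataFrame(cols, index=index)
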