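"""Classifier evaluation and screening-report aggregation.

Multiclass performance is summarized by a confusion matrix (rows = true
class, columns = predicted class) reduced one-vs-rest per class to true/false
positives/negatives, from which

    sensitivity = Tp / (Tp + Fn)        specificity = Tn / (Tn + Fp)
    precision   = Tp / (Tp + Fp)        accuracy    = trace / total

Macro averages are unweighted means over the classes. Screening reports
render per-measurement class probabilities as percentages (two decimals)
and aggregate each group with the arithmetic mean and the population
standard deviation (divisor n, not n-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from lungscreen.audio_io import CLASS_ORDER
from lungscreen.errors import ContractError, UndefinedMetricError

DEFAULT_CLASS_ORDER = tuple(c.value for c in CLASS_ORDER)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Count matrix with its class ordering (rows true, columns predicted)."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ContractError(f"counts must be {k}x{k} for {k} classes")
        if np.any(counts < 0):
            raise ContractError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_label: str) -> tuple[int, int, int, int]:
        """(Tp, Tn, Fp, Fn) for one class against the rest."""
        i = self.class_order.index(class_label)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i, :].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro one-vs-rest metrics plus overall accuracy."""

    per_class: dict[str, dict[str, float]]  # class -> {sensitivity, specificity, precision}
    accuracy: float
    macro_sensitivity: float
    macro_specificity: float
    macro_precision: float

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.per_class).T
        frame.index.name = "class"
        return frame


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
) -> ConfusionMatrix:
    """Counts of (true, predicted) pairs over a fixed class ordering."""
    true_labels = [str(l) for l in true_labels]
    predicted_labels = [str(l) for l in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise ContractError("true and predicted label sequences differ in length")
    if len(true_labels) == 0:
        raise ContractError("need at least one labeled sample")
    unknown = set(true_labels) | set(predicted_labels)
    unknown -= set(class_order)
    if unknown:
        raise ContractError(f"labels outside the class set: {sorted(unknown)}")
    counts = _sk_confusion_matrix(true_labels, predicted_labels, labels=list(class_order))
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def _ratio(numer: int, denom: int, metric: str, class_label: str) -> float:
    if denom == 0:
        raise UndefinedMetricError(metric, class_label)
    return numer / denom


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest sensitivity/specificity/precision per class, macro means,
    and overall accuracy (trace over total).

    A zero denominator (e.g. a class never predicted) raises
    :class:`UndefinedMetricError` naming the class and metric rather than
    silently reporting 0.
    """
    per_class: dict[str, dict[str, float]] = {}
    for label in cm.class_order:
        tp, tn, fp, fn = cm.one_vs_rest(label)
        per_class[label] = {
            "sensitivity": _ratio(tp, tp + fn, "sensitivity", label),
            "specificity": _ratio(tn, tn + fp, "specificity", label),
            "precision": _ratio(tp, tp + fp, "precision", label),
        }
    accuracy = float(np.trace(cm.counts)) / cm.total
    return MetricsReport(
        per_class=per_class,
        accuracy=accuracy,
        macro_sensitivity=macro_average([m["sensitivity"] for m in per_class.values()]),
        macro_specificity=macro_average([m["specificity"] for m in per_class.values()]),
        macro_precision=macro_average([m["precision"] for m in per_class.values()]),
    )


def macro_average(values: Sequence[float]) -> float:
    """Unweighted mean of a per-class metric."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ContractError("macro average of an empty sequence")
    return float(values.mean())


@dataclass(frozen=True)
class ScreeningReport:
    """Per-measurement class-probability percentages with group mean/SD rows.

    ``rows`` holds one DataFrame per group (percent values, 2 decimals);
    ``aggregates`` holds per group a (mean, sd) pair per class, where sd is
    the population form.
    """

    class_order: tuple[str, ...]
    rows: dict[str, pd.DataFrame]
    aggregates: dict[str, dict[str, tuple[float, float]]]

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per measurement plus a Mean (SD) row per group."""
        parts = []
        for group, frame in self.rows.items():
            block = frame.copy()
            block.insert(0, "group", group)
            block.insert(1, "row", [str(i + 1) for i in range(len(frame))])
            agg = pd.DataFrame(
                [
                    {
                        "group": group,
                        "row": "Mean (SD)",
                        **{
                            c: f"{self.aggregates[group][c][0]:.2f} ({self.aggregates[group][c][1]:.2f})"
                            for c in self.class_order
                        },
                    }
                ]
            )
            parts.append(pd.concat([block.astype({c: object for c in self.class_order}), agg]))
        return pd.concat(parts, ignore_index=True)


def screening_report(
    groups: Mapping[str, Sequence[Sequence[float]]],
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
) -> ScreeningReport:
    """Aggregate class probabilities into a screening report.

    ``groups`` maps a group label (e.g. the target condition, or a
    volunteer/measurement point) to a list of probability vectors aligned to
    ``class_order``. Probabilities are rendered as percentages rounded to
    two decimals; each group gets an arithmetic mean and a population
    standard deviation per class, computed on the rounded percentages and
    rounded to two decimals.
    """
    class_order = tuple(class_order)
    rows: dict[str, pd.DataFrame] = {}
    aggregates: dict[str, dict[str, tuple[float, float]]] = {}
    for group, prob_rows in groups.items():
        if len(prob_rows) == 0:
            raise ContractError(f"group {group!r} has no measurements")
        percents = np.round(np.asarray(prob_rows, dtype=np.float64) * 100.0, 2)
        if percents.ndim != 2 or percents.shape[1] != len(class_order):
            raise ContractError(
                f"group {group!r}: each row needs {len(class_order)} probabilities"
            )
        rows[group] = pd.DataFrame(percents, columns=class_order)
        aggregates[group] = {
            c: (
                float(np.round(percents[:, j].mean(), 2)),
                float(np.round(percents[:, j].std(ddof=0), 2)),
            )
            for j, c in enumerate(class_order)
        }
    return ScreeningReport(class_order=class_order, rows=rows, aggregates=aggregates)
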