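"""Confusion-table evaluation metrics and comparison reports.

Multiclass aggregation uses macro-averaged precision and recall; the F1
score is computed from the aggregated precision and recall via
``F1 = 2 P R / (P + R)`` (not the macro average of per-class F1s).
Fractions are stored internally; reports render percentages with two
decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionTable",
    "EvalReport",
    "confusion",
    "evaluate",
    "f1_from_pr",
    "relative_improvement",
    "format_report_table",
    "reports_to_dataframe",
]


@dataclass
class ConfusionTable:
    """G x G count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion counts must be a square matrix")
        if self.counts.min() < 0:
            raise ValueError("confusion counts must be nonnegative")
        if not self.class_names:
            self.class_names = [f"class_{g}" for g in range(self.counts.shape[0])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """Aggregate and per-class classification metrics, as fractions in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    model_name: str = ""

    def as_percent_row(self) -> dict:
        return {
            "model": self.model_name,
            "accuracy": round(100 * self.accuracy, 2),
            "precision": round(100 * self.precision, 2),
            "recall": round(100 * self.recall, 2),
            "f1": round(100 * self.f1, 2),
        }


def confusion(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    n_classes: int | None = None,
    class_names: list[str] | None = None,
) -> ConfusionTable:
    """Count matrix ``counts[g][h] = #{i : true=g, pred=h}``."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label vectors must have equal length")
    if t.size == 0:
        raise ValueError("cannot build a confusion table from empty vectors")
    if n_classes is None:
        n_classes = int(max(t.max(), p.max())) + 1
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionTable(counts, class_names or [])


def f1_from_pr(precision: float, recall: float) -> float:
    """``2 P R / (P + R)``; zero when both are zero.  Scale-invariant, so it
    accepts fractions or percentages alike."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(table: ConfusionTable, model_name: str = "") -> EvalReport:
    """Accuracy, macro precision/recall, and F1 from a confusion table.

    Per-class precision = TP/(TP+FP) and recall = TP/(TP+FN); classes with
    a zero denominator score 0 with a warning.  F1 combines the
    macro-aggregated precision and recall.
    """
    C = table.counts
    total = table.total
    if total == 0:
        raise ValueError("confusion table is empty")
    tp = np.diag(C).astype(float)
    pred_totals = C.sum(axis=0).astype(float)  # TP + FP per class
    true_totals = C.sum(axis=1).astype(float)  # TP + FN per class
    if np.any(pred_totals == 0) or np.any(true_totals == 0):
        warnings.warn(
            "zero-denominator class in precision/recall; metric set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_prec = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        per_rec = np.where(true_totals > 0, tp / true_totals, 0.0)
    precision = float(per_prec.mean())
    recall = float(per_rec.mean())
    return EvalReport(
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1_from_pr(precision, recall),
        per_class_precision=per_prec,
        per_class_recall=per_rec,
        model_name=model_name,
    )


def relative_improvement(a: float, b: float) -> float:
    """Relative improvement ``(a - b) / b`` of a over baseline b (b > 0)."""
    if b <= 0:
        raise ValueError("baseline must be positive")
    return (a - b) / b


def reports_to_dataframe(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """One row per model, percentage-scaled metrics with 2-decimal display."""
    return pd.DataFrame([r.as_percent_row() for r in reports])


def format_report_table(reports: Sequence[EvalReport]) -> str:
    """Aligned-column text table (model x accuracy/precision/recall/F1, in %)."""
    df = reports_to_dataframe(reports)
    header = f"{'Model':<12}{'Accuracy':>10}{'Precision':>11}{'Recall':>9}{'F1':>9}"
    lines = [header, "-" * len(header)]
    for _, row in df.iterrows():
        lines.append(
            f"{row['model']:<12}{row['accuracy']:>9.2f}%{row['precision']:>10.2f}%"
            f"{row['recall']:>8.2f}%{row['f1']:>8.2f}%"
        )
    return "\n".join(lines)
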