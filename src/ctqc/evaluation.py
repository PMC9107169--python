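"""Confusion matrices and classification performance metrics.

Per-class metrics follow the standard one-vs-rest definitions:
precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2·precision·recall/(precision+recall); overall accuracy is the number
of correct predictions over the total. Aggregates are macro-averaged
(unweighted class means) by default, switchable to micro. A ratio with a
zero denominator is reported as 0 and flagged. All values are percentages;
rounding (half-up, to the displayed precision) happens only at rendering.

Dataset-level evaluation scores body part and contrast separately against a
label manifest, plus an *overall* accuracy that counts a series correct only
when both labels match.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "metrics",
    "evaluate_dataset",
    "format_percent",
]


def format_percent(value: float, decimals: int = 1) -> float:
    """Round a percentage half-up to the displayed precision."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = tuple(self.classes)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be n_classes × n_classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\predicted", *self.classes])
            for cls, row in zip(self.classes, self.counts):
                writer.writerow([cls, *row.tolist()])
        return path


@dataclass
class MetricsReport:
    """Per-class and aggregate performance, all values in percent."""

    classes: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    precision: float
    recall: float
    f1: float
    accuracy: float
    average: str = "macro"
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "per_class": self.per_class,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "average": self.average,
            "undefined": self.undefined,
        }


def confusion_matrix(true_labels, predicted_labels, class_set) -> ConfusionMatrix:
    """Count (true, predicted) pairs over an explicit class set."""
    classes = tuple(class_set)
    index = {c: i for i, c in enumerate(classes)}
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def metrics(cm: ConfusionMatrix, average: str = "macro") -> MetricsReport:
    """Per-class precision/recall/F1 and aggregate metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    undefined: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    precisions, recalls, f1s = [], [], []
    for i, cls in enumerate(cm.classes):
        if tp[i] + fp[i] > 0:
            prec = tp[i] / (tp[i] + fp[i])
        else:
            prec = 0.0
            undefined.append(f"precision[{cls}]")
        if tp[i] + fn[i] > 0:
            rec = tp[i] / (tp[i] + fn[i])
        else:
            rec = 0.0
            undefined.append(f"recall[{cls}]")
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[cls] = {
            "precision": 100.0 * prec,
            "recall": 100.0 * rec,
            "f1": 100.0 * f1,
        }
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)

    if average == "macro":
        agg_p = float(np.mean(precisions))
        agg_r = float(np.mean(recalls))
        agg_f = float(np.mean(f1s))
    else:  # micro: pooled counts; equals accuracy for single-label classification
        agg_p = float(tp.sum() / (tp.sum() + fp.sum()))
        agg_r = float(tp.sum() / (tp.sum() + fn.sum()))
        agg_f = 2 * agg_p * agg_r / (agg_p + agg_r) if agg_p + agg_r > 0 else 0.0

    accuracy = float(tp.sum() / cm.total)
    return MetricsReport(
        classes=cm.classes,
        per_class=per_class,
        precision=100.0 * agg_p,
        recall=100.0 * agg_r,
        f1=100.0 * agg_f,
        accuracy=100.0 * accuracy,
        average=average,
        undefined=undefined,
    )


def f1_from_percent(precision_pct: float, recall_pct: float) -> float:
    """F1 (percent) from precision and recall already expressed in percent."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def evaluate_dataset(manifest, qc_results, average: str = "macro"):
    """Score QC results against a label manifest.

    *manifest* is a DataFrame or CSV path with columns
    ``series_id, body_part, contrast`` (contrast as 0/1 or contrast /
    non_contrast labels). Returns
    ``(body_report, body_cm, contrast_report, contrast_cm, overall_pct)``
    where *overall* counts a series correct only when both the body-part and
    the contrast label match.
    """
    from .ensemble import CONTRAST_CLASSES
    from .phantom import BODY_PARTS

    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, dtype={"series_id": str})
    manifest = manifest.set_index("series_id")

    def contrast_label(value) -> str:
        if isinstance(value, str) and value in CONTRAST_CLASSES:
            return value
        return "contrast" if int(value) else "non_contrast"

    body_true, body_pred, con_true, con_pred = [], [], [], []
    both_correct = 0
    for result in qc_results:
        if result.series_id not in manifest.index:
            raise ValueError(f"series {result.series_id!r} not in manifest")
        row = manifest.loc[result.series_id]
        bt, ct = str(row["body_part"]), contrast_label(row["contrast"])
        body_true.append(bt)
        body_pred.append(result.body_part)
        con_true.append(ct)
        con_pred.append(result.contrast)
        both_correct += int(bt == result.body_part and ct == result.contrast)

    body_cm = confusion_matrix(body_true, body_pred, BODY_PARTS)
    con_cm = confusion_matrix(con_true, con_pred, CONTRAST_CLASSES)
    overall = 100.0 * both_correct / len(qc_results)
    return metrics(body_cm, average), body_cm, metrics(con_cm, average), con_cm, overall


def write_metrics_json(report: MetricsReport, path: str | Path, **extra) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {**report.to_dict(), **extra}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path
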