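"""Evaluation of automatic annotations against manual ground truth.

Manual labels arrive as a CSV of (frame_index, label) written by a human
annotator. Because fixation classes in real scenes are heavily imbalanced
(road and building dominate; navigation devices are rare but critical), the
report carries accuracy, per-class precision/recall/F1 and both macro
(class-equal) and weighted (support-weighted) averages, plus row-normalized
confusion matrices rendered with zero cells left blank.

Zero-division convention: a class that is never predicted gets precision 0,
a class absent from the truth gets recall 0 (``zero_division="0"``), and
classes with zero support are excluded from macro/weighted averages;
``zero_division="exclude"`` instead drops undefined per-class values from
the macro mean. For single-label data the weighted recall equals accuracy
exactly (both are correct counts over total counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .taxonomy import MergeMap

__all__ = [
    "NONE_LABEL",
    "ConfusionMatrix",
    "MetricsReport",
    "build_confusion",
    "compute_metrics",
    "normalize_confusion",
    "plot_confusion",
    "evaluate_labels",
]

#: Column used when a method makes no prediction for a fixation.
NONE_LABEL = "none"


@dataclass
class ConfusionMatrix:
    """Square integer counts; rows are truth, columns are predictions."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class MetricsReport:
    """Accuracy plus per-class and averaged precision/recall/F1."""

    accuracy: float
    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def to_frame(self) -> pd.DataFrame:
        """Per-class table plus macro/weighted summary rows."""
        rows = [
            {
                "class": c,
                "precision": self.precision[c],
                "recall": self.recall[c],
                "f1": self.f1[c],
                "support": self.support[c],
            }
            for c in self.classes
        ]
        rows.append(
            {
                "class": "macro avg",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
                "support": sum(self.support.values()),
            }
        )
        rows.append(
            {
                "class": "weighted avg",
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
                "support": sum(self.support.values()),
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "per_class": {
                c: {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "support": self.support[c],
                }
                for c in self.classes
            },
        }


def build_confusion(
    pred: Sequence[str | None], truth: Sequence[str], classes: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Tally (truth, prediction) pairs into a confusion matrix.

    ``None`` or empty predictions land in an explicit ``none`` column. The
    class order is the sorted union of truth and predicted labels unless
    given explicitly.
    """
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    pred = [NONE_LABEL if (p is None or p == "") else p for p in pred]
    if classes is None:
        classes = sorted(set(truth) | set(pred))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, t in zip(pred, truth):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def compute_metrics(cm: ConfusionMatrix, zero_division: str = "0") -> MetricsReport:
    """Derive accuracy and per-class / macro / weighted metrics from counts."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    if zero_division not in ("0", "exclude"):
        raise ValueError(f"unknown zero_division {zero_division!r}")

    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        rec = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        pr = prec + rec
        f1 = np.where(pr > 0, 2 * prec * rec / np.where(pr > 0, pr, 1), 0.0)

    supported = row > 0  # averages run over classes present in the truth
    if zero_division == "exclude":
        macro_p = float(prec[supported & (col > 0)].mean()) if (supported & (col > 0)).any() else 0.0
    else:
        macro_p = float(prec[supported].mean())
    macro_r = float(rec[supported].mean())
    macro_f = float(f1[supported].mean())
    weights = row[supported] / row[supported].sum()
    weighted_p = float((prec[supported] * weights).sum())
    weighted_r = float((rec[supported] * weights).sum())
    weighted_f = float((f1[supported] * weights).sum())

    return MetricsReport(
        accuracy=float(diag.sum() / cm.total),
        classes=list(cm.classes),
        precision={c: float(prec[i]) for i, c in enumerate(cm.classes)},
        recall={c: float(rec[i]) for i, c in enumerate(cm.classes)},
        f1={c: float(f1[i]) for i, c in enumerate(cm.classes)},
        support={c: int(row[i]) for i, c in enumerate(cm.classes)},
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        weighted_precision=weighted_p,
        weighted_recall=weighted_r,
        weighted_f1=weighted_f,
    )


def normalize_confusion(cm: ConfusionMatrix) -> np.ndarray:
    """Row-normalize counts to [0, 1]; rows with zero support stay zero."""
    counts = cm.counts.astype(float)
    row = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)


def plot_confusion(
    cm: ConfusionMatrix,
    path: str | Path | None = None,
    normalized: bool = True,
    title: str | None = None,
):
    """Render the (normalized) confusion matrix; zero cells are left blank."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = normalize_confusion(cm) if normalized else cm.counts.astype(float)
    k = len(cm.classes)
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * k + 2), max(3.5, 0.6 * k + 1.5)))
    ax.imshow(values, cmap="Blues", vmin=0, vmax=values.max() or 1)
    ax.set_xticks(range(k), cm.classes, rotation=45, ha="right")
    ax.set_yticks(range(k), cm.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("truth")
    if title:
        ax.set_title(title)
    for i in range(k):
        for j in range(k):
            if values[i, j] > 0:  # zero cells left blank
                ax.text(
                    j,
                    i,
                    f"{values[i, j]:.2f}" if normalized else f"{int(values[i, j])}",
                    ha="center",
                    va="center",
                    fontsize=8,
                    color="black" if values[i, j] < 0.6 * (values.max() or 1) else "white",
                )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig


def evaluate_labels(
    pred: Sequence[str | None],
    truth: Sequence[str],
    merge_map: MergeMap | None = None,
    zero_division: str = "0",
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix + metrics, optionally in the merged label space."""
    if merge_map is not None:
        pred = [None if p in (None, "") else merge_map(p) for p in pred]
        truth = [merge_map(t) for t in truth]
    cm = build_confusion(pred, truth)
    return cm, compute_metrics(cm, zero_division=zero_division)
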