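"""Segmentation quality metrics and multi-run report tables.

Pixelwise overlap scores between a predicted vessel mask and ground truth:
Dice = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), sensitivity = TP/(TP+FN) and
accuracy = (TP+TN)/total, all reported in percent.  Degenerate conventions:
when both masks are empty (TP+FP+FN == 0) Dice, IoU and sensitivity are all
100; when truth is empty but predictions exist (TP+FN == 0, FP > 0)
sensitivity is 0.

Multi-run experiments are summarized by :func:`build_report`: one row per
run plus an arithmetic-mean "Average" row, rounded to two decimals only at
presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

METRIC_COLUMNS = ("Dice coefficient", "IoU", "Sensitivity", "Accuracy")

__all__ = ["METRIC_COLUMNS", "ConfusionCounts", "MetricsReport", "confusion", "metrics", "build_report"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts with True meaning vessel."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(dice, iou, sensitivity, accuracy) in percent from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion table")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    union = tp + fp + fn
    if union == 0:  # both masks empty: perfect agreement by convention
        dice = iou = 100.0
    else:
        dice = 100.0 * 2 * tp / (2 * tp + fp + fn)
        iou = 100.0 * tp / union
    positives = tp + fn
    if positives == 0:
        sensitivity = 100.0 if union == 0 else 0.0
    else:
        sensitivity = 100.0 * tp / positives
    accuracy = 100.0 * (tp + tn) / counts.total
    return dice, iou, sensitivity, accuracy


@dataclass(frozen=True)
class MetricsReport:
    """Per-run metric rows plus their arithmetic-mean average row.

    ``per_run[r]`` is a (dice, iou, sensitivity, accuracy) tuple in percent;
    ``average`` is the column-wise arithmetic mean at full precision.
    """

    per_run: tuple[tuple[float, float, float, float], ...]
    average: tuple[float, float, float, float]

    def to_dataframe(self, decimals: int | None = 2) -> pd.DataFrame:
        """Tabulate as rows Run-1..Run-n plus Average, columns per metric."""
        rows = [*self.per_run, self.average]
        index = [f"Run-{r + 1}" for r in range(len(self.per_run))] + ["Average"]
        df = pd.DataFrame(rows, index=index, columns=list(METRIC_COLUMNS))
        df.index.name = "No. of runs"
        return df.round(decimals) if decimals is not None else df

    def to_csv(self, path: str | Path, decimals: int | None = 2) -> None:
        self.to_dataframe(decimals).to_csv(path)


def build_report(runs: Sequence[tuple[np.ndarray, np.ndarray]]) -> MetricsReport:
    """Score each (pred, truth) mask pair and append the average row."""
    if len(runs) == 0:
        raise ValueError("need at least one run to build a report")
    per_run = tuple(metrics(confusion(pred, truth)) for pred, truth in runs)
    average = tuple(float(np.mean([row[c] for row in per_run])) for c in range(4))
    return MetricsReport(per_run=per_run, average=average)
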