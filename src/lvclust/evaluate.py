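"""Segmentation and diagnostic scoring.

Per-class Dice coefficients (2|P∩T| / (|P|+|T|)) for the three ventricle
zones, pooled over a patient's slices or reported per slice, plus the
standard confusion-matrix metrics (accuracy, recall, precision, F1) used to
score the binary LVNC call at patient level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .io import EL, IC, TZ, SegmentationStack, ValidationError

__all__ = ["DiceReport", "ConfusionCounts", "DiagnosticMetrics", "dice_per_class",
           "dice_per_slice", "diagnostic_metrics", "compare_dice_changes", "DiceChanges"]


@dataclass(frozen=True)
class DiceReport:
    dice_el: float
    dice_ic: float
    dice_tz: float

    @property
    def dice_mean(self) -> float:
        return (self.dice_el + self.dice_ic + self.dice_tz) / 3.0


def _dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    p = int(pred_mask.sum())
    t = int(truth_mask.sum())
    if p + t == 0:
        return 1.0  # agreement on absence (e.g. blanked slices)
    inter = int(np.logical_and(pred_mask, truth_mask).sum())
    return 2.0 * inter / (p + t)


def _check_shapes(pred: SegmentationStack, truth: SegmentationStack) -> None:
    if pred.voxels.shape != truth.voxels.shape:
        raise ValidationError(
            f"stack shape mismatch: {pred.voxels.shape} vs {truth.voxels.shape}")


def dice_per_class(pred: SegmentationStack, truth: SegmentationStack) -> DiceReport:
    """Per-class Dice pooled over all slices of the patient."""
    _check_shapes(pred, truth)
    return DiceReport(*(
        _dice(pred.voxels == c, truth.voxels == c) for c in (EL, IC, TZ)))


def dice_per_slice(pred: SegmentationStack, truth: SegmentationStack) -> pd.DataFrame:
    """Slice-wise Dice table (columns: slice, dice_el, dice_ic, dice_tz,
    dice_mean), for end-slice and area analyses."""
    _check_shapes(pred, truth)
    rows = []
    for i in range(pred.n_slices):
        scores = [_dice(pred.voxels[i] == c, truth.voxels[i] == c) for c in (EL, IC, TZ)]
        rows.append({"slice": i, "dice_el": scores[0], "dice_ic": scores[1],
                     "dice_tz": scores[2], "dice_mean": float(np.mean(scores))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConfusionCounts:
    """Patient-level confusion counts; positive class = LVNC."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy, recall, precision, F1; a metric whose denominator is zero
    is reported as None (absent), never as 0."""

    accuracy: float
    recall: Optional[float]
    precision: Optional[float]
    f1: Optional[float]

    def rounded(self, ndigits: int = 3) -> dict:
        def r(v):
            # round-half-up at the report precision
            return None if v is None else float(np.floor(v * 10**ndigits + 0.5) / 10**ndigits)
        return {"accuracy": r(self.accuracy), "recall": r(self.recall),
                "precision": r(self.precision), "f1": r(self.f1)}


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    if counts.total == 0:
        raise ValidationError("cannot compute metrics on an empty confusion matrix")
    accuracy = (counts.tp + counts.tn) / counts.total
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return DiagnosticMetrics(accuracy, recall, precision, f1)


class DiceChanges(NamedTuple):
    table: pd.DataFrame
    improved: int
    worsened: int
    unchanged: int
    mean_delta_affected: float


def compare_dice_changes(before: Sequence[DiceReport],
                         after: Sequence[DiceReport]) -> DiceChanges:
    """Paired before/after comparison of mean Dice per image.

    Produces the per-image (before, after, delta, improved) table behind a
    post-processing change scatter, plus improvement counts and the mean
    delta over affected (changed) images.
    """
    if len(before) != len(after):
        raise ValidationError(f"paired lists differ in length: {len(before)} vs {len(after)}")
    rows = []
    for i, (b, a) in enumerate(zip(before, after)):
        delta = a.dice_mean - b.dice_mean
        rows.append({"image": i, "before": b.dice_mean, "after": a.dice_mean,
                     "delta": delta, "improved": delta > 0})
    table = pd.DataFrame(rows)
    improved = int((table["delta"] > 0).sum())
    worsened = int((table["delta"] < 0).sum())
    unchanged = int((table["delta"] == 0).sum())
    affected = table.loc[table["delta"] != 0, "delta"]
    mean_delta = float(affected.mean()) if len(affected) else 0.0
    return DiceChanges(table, improved, worsened, unchanged, mean_delta)
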