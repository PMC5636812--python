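"""Pixel-level accuracy assessment of extracted shadow masks.

Predicted masks are scored against reference (visually interpreted) masks
with set operations on pixels — TP = pred ∩ truth, FP = pred \\ truth,
FN = truth \\ pred, TN the remainder — and summarized as precision,
recall and their weighted harmonic mean Fβ (β = 1 weights them equally).

Sample scores are rounded to two decimals before averaging, the precision
at which such scores are conventionally tabulated; per-image means and the
overall mean of image means are reported as percentages to one decimal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "AccuracyScores",
    "AccuracySummary",
    "confusion",
    "precision",
    "recall",
    "f_beta",
    "score_masks",
    "scores_from_pr",
    "summarize",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts for one evaluated sample."""

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


@dataclass(frozen=True)
class AccuracyScores:
    precision: float
    recall: float
    f_beta: float
    beta: float = 1.0


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Confusion counts between two same-shape binary masks."""
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape} vs {truth.shape}"
        )
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN with a warning when nothing was predicted."""
    denom = c.tp + c.fp
    if denom == 0:
        warnings.warn("precision undefined: no predicted positives", stacklevel=2)
        return math.nan
    return c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN with a warning when the truth mask is empty."""
    denom = c.tp + c.fn
    if denom == 0:
        warnings.warn("recall undefined: no true positives in reference", stacklevel=2)
        return math.nan
    return c.tp / denom


def f_beta(p: float, r: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean (1+β²)·P·R / (β²·P + R); 0 when P = R = 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if math.isnan(p) or math.isnan(r):
        return math.nan
    denom = beta * beta * p + r
    if denom == 0.0:
        return 0.0
    return (1.0 + beta * beta) * p * r / denom


def score_masks(
    pred_mask: np.ndarray, truth_mask: np.ndarray, beta: float = 1.0
) -> AccuracyScores:
    """Confusion → precision/recall/Fβ for one mask pair."""
    c = confusion(pred_mask, truth_mask)
    p = precision(c)
    r = recall(c)
    return AccuracyScores(precision=p, recall=r, f_beta=f_beta(p, r, beta), beta=beta)


def scores_from_pr(p: float, r: float, beta: float = 1.0) -> AccuracyScores:
    """Build scores from already-tabulated precision and recall values."""
    return AccuracyScores(precision=p, recall=r, f_beta=f_beta(p, r, beta), beta=beta)


@dataclass(frozen=True)
class AccuracySummary:
    """Per-image and overall mean Fβ, as percentages to one decimal."""

    per_image_pct: dict[str, float]
    overall_pct: float


def summarize(
    samples: Mapping[str, Sequence[AccuracyScores]] | Iterable[Sequence[AccuracyScores]],
) -> AccuracySummary:
    """Mean Fβ per image and overall.

    ``samples`` maps an image label to that image's per-sample scores
    (an iterable of score lists is accepted and labelled by position).
    Per-sample Fβ is rounded to 2 decimals, averaged within each image;
    the overall value is the mean of image means.  Samples with undefined
    (NaN) scores are excluded with a warning.
    """
    if not isinstance(samples, Mapping):
        samples = {str(i): s for i, s in enumerate(samples)}
    if not samples:
        raise ValueError("at least one image of samples is required")
    per_image: dict[str, float] = {}
    for label, scores in samples.items():
        vals = []
        for s in scores:
            if math.isnan(s.f_beta):
                warnings.warn(
                    f"sample with undefined score excluded from image {label!r}",
                    stacklevel=2,
                )
                continue
            vals.append(round(s.f_beta, 2))
        if not vals:
            raise ValueError(f"image {label!r} has no scoreable samples")
        per_image[label] = round(100.0 * float(np.mean(vals)), 1)
    overall = round(float(np.mean(list(per_image.values()))), 1)
    return AccuracySummary(per_image_pct=per_image, overall_pct=overall)
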