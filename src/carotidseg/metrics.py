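"""Segmentation evaluation on mask pairs, and the paired t test.

Scores follow the pixel-set formulations: with final contour set C_F,
ground-truth set C_GT and N total pixels,

    Dice        = 2|C_F n C_GT| / (|C_F| + |C_GT|)
    Sensitivity = |C_F n C_GT| / |C_GT|
    Specificity = (N - |C_F| - |C_GT| + |C_F n C_GT|) / (N - |C_GT|)
    Accuracy    = (|C_F n C_GT| + N - |C_F| - |C_GT| + |C_F n C_GT|) / N

which coincide with the usual confusion-count forms (TP = |C_F n C_GT|,
FP = |C_F| - TP, FN = |C_GT| - TP, TN = N - TP - FP - FN).  Fractions are
stored in [0, 1]; multiply by 100 for the percentages usually reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["SegScores", "PairedTestResult", "score_masks", "paired_t_test"]


@dataclass(frozen=True)
class SegScores:
    dice: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int
    flags: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


def score_masks(pred: np.ndarray, truth: np.ndarray) -> SegScores:
    """Overlap scores between a predicted and a ground-truth binary mask.

    Degenerate denominators are resolved by convention and flagged: an empty
    ground truth gives sensitivity 1 if the prediction is also empty, else 0;
    two empty masks score Dice 1.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    n = pred.size
    cf = int(pred.sum())
    cgt = int(truth.sum())
    inter = int((pred & truth).sum())

    flags: list[str] = []
    if cf + cgt == 0:
        dice = 1.0
        flags.append("both-empty")
    else:
        dice = 2.0 * inter / (cf + cgt)
    if cgt == 0:
        sensitivity = 1.0 if cf == 0 else 0.0
        flags.append("empty-truth")
    else:
        sensitivity = inter / cgt
    if n - cgt == 0:
        specificity = 1.0 if cf == n else 0.0
        flags.append("full-truth")
    else:
        specificity = (n - cf - cgt + inter) / (n - cgt)
    accuracy = (inter + (n - cf - cgt + inter)) / n

    tp = inter
    fp = cf - inter
    fn = cgt - inter
    tn = n - tp - fp - fn
    return SegScores(
        dice=dice,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_difference: float
    flags: tuple[str, ...] = ()


def paired_t_test(scores_a, scores_b) -> PairedTestResult:
    """Classic paired t test on per-item differences a_i - b_i (two-sided).

    Zero-variance differences are degenerate: p = 1 when the mean difference
    is also zero (identical samples), p = 0 otherwise; both cases flagged.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, df, 1.0, 0.0, ("zero-variance-zero-mean",))
        t = float(np.sign(mean)) * np.inf
        return PairedTestResult(t, df, 0.0, mean, ("zero-variance",))
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTestResult(float(t), df, p, mean)
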