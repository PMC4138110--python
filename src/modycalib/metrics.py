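"""Confusion counts and performance measures: missing rate, FNR, FPR, MCC.

Unscored records (predictor not applicable) are excluded from the confusion
table and reported separately through the missing rate, so error rates are
always conditional on the predictor having returned a score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "PerformanceRow",
    "tabulate",
    "missing_rate",
    "fnr",
    "fpr",
    "mcc",
    "sensitivity",
    "specificity",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN for one (method, scope, threshold) evaluation.

    tp+fn is the number of scored disease records, fp+tn the number of
    scored controls; unscored records are tallied separately.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_unscored_cases: int = 0
    n_unscored_controls: int = 0

    def __post_init__(self) -> None:
        for f in ("tp", "fp", "fn", "tn", "n_unscored_cases", "n_unscored_controls"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def total(self) -> int:
        return (self.tp + self.fp + self.fn + self.tn
                + self.n_unscored_cases + self.n_unscored_controls)


@dataclass(frozen=True)
class PerformanceRow:
    """One row of a performance report (method x gene-or-pooled scope)."""

    method: str
    scope: str
    threshold: float
    missing_rate: float
    fnr: float
    fpr: float
    mcc: float
    n_cases: int
    n_controls: int


def tabulate(scores, labels, threshold: float) -> ConfusionCounts:
    """Build the confusion table at one cutoff.

    ``scores`` is a converted-score column (NaN = unscored), ``labels`` a
    boolean column (True = disease).  Deleterious call is strict '>'.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError(f"length mismatch: {s.shape} scores vs {y.shape} labels")
    scored = ~np.isnan(s)
    pos = scored & (s > threshold)
    neg = scored & ~pos
    return ConfusionCounts(
        tp=int(np.sum(pos & y)),
        fp=int(np.sum(pos & ~y)),
        fn=int(np.sum(neg & y)),
        tn=int(np.sum(neg & ~y)),
        n_unscored_cases=int(np.sum(~scored & y)),
        n_unscored_controls=int(np.sum(~scored & ~y)),
    )


def missing_rate(cc: ConfusionCounts) -> float:
    """Fraction of all records the predictor returned no score for."""
    if cc.total == 0:
        raise ValueError("missing rate undefined for an empty table")
    return (cc.n_unscored_cases + cc.n_unscored_controls) / cc.total


def fnr(cc: ConfusionCounts) -> float:
    """fn / (tp + fn) over scored disease records; NaN if none scored."""
    d = cc.tp + cc.fn
    return cc.fn / d if d else math.nan


def fpr(cc: ConfusionCounts) -> float:
    """fp / (fp + tn) over scored controls; NaN if none scored."""
    d = cc.fp + cc.tn
    return cc.fp / d if d else math.nan


def sensitivity(cc: ConfusionCounts) -> float:
    d = cc.tp + cc.fn
    return cc.tp / d if d else math.nan


def specificity(cc: ConfusionCounts) -> float:
    d = cc.fp + cc.tn
    return cc.tn / d if d else math.nan


def mcc(cc: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any margin is empty.

    Equals the Pearson correlation between the truth and prediction
    indicator vectors, hence lies in [-1, 1] and is robust to the heavy
    case/control imbalance of mutation panels.
    """
    tp, fp, fn, tn = cc.tp, cc.fp, cc.fn, cc.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)
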