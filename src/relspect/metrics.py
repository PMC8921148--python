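"""Classification performance statistics and inter-rater agreement.

Conventions: "positive" is the reduced-uptake class.  Metrics are computed
from the four confusion counts and reported in percent; display rounding is
half-up to one decimal (the unrounded values are retained for comparisons).
A metric with a zero denominator is reported as absent (None), not as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "confusion",
    "performance",
    "marginal_error",
    "percent_agreement_and_kappa",
    "round_half_up",
]

_LABELS = ("negative", "positive")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero-at-.5 upward (matches printed tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TN/TP/FN/FP counts from which every metric derives."""

    tn: int
    tp: int
    fn: int
    fp: int

    def __post_init__(self):
        for name in ("tn", "tp", "fn", "fp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tn + self.tp + self.fn + self.fp


@dataclass(frozen=True)
class PerformanceReport:
    """Percent metrics; an undefined metric (zero denominator) is None."""

    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def rounded(self, decimals: int = 1) -> dict:
        return {
            k: (None if v is None else round_half_up(v, decimals))
            for k, v in self.__dict__.items()
        }


def confusion(truth: Sequence, predictions: Sequence) -> ConfusionCounts:
    """Count TN/TP/FN/FP over paired label sequences."""
    truth = list(truth)
    predictions = list(predictions)
    if len(truth) != len(predictions):
        raise ValueError(
            f"length mismatch: {len(truth)} truth vs {len(predictions)} predictions"
        )
    for lab in list(truth) + list(predictions):
        if lab not in _LABELS:
            raise ValueError(f"unknown label {lab!r}; expected one of {_LABELS}")
    tn = sum(1 for t, p in zip(truth, predictions) if t == "negative" and p == "negative")
    tp = sum(1 for t, p in zip(truth, predictions) if t == "positive" and p == "positive")
    fn = sum(1 for t, p in zip(truth, predictions) if t == "positive" and p == "negative")
    fp = sum(1 for t, p in zip(truth, predictions) if t == "negative" and p == "positive")
    return ConfusionCounts(tn=tn, tp=tp, fn=fn, fp=fp)


def _ratio_pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def performance(c: ConfusionCounts) -> PerformanceReport:
    """Accuracy, sensitivity, specificity, PPV, NPV in percent."""
    return PerformanceReport(
        accuracy=100.0 * (c.tn + c.tp) / c.total,
        sensitivity=_ratio_pct(c.tp, c.tp + c.fn),
        specificity=_ratio_pct(c.tn, c.tn + c.fp),
        ppv=_ratio_pct(c.tp, c.tp + c.fp),
        npv=_ratio_pct(c.tn, c.tn + c.fn),
    )


def marginal_error(acc: float, n: int) -> float:
    """Maximum marginal error of an accuracy estimate at 95% confidence.

    d = 1.96 * sqrt(acc * (1 - acc) / n).
    """
    if not 0.0 <= acc <= 1.0:
        raise ValueError(f"acc must be in [0, 1], got {acc}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return 1.96 * float(np.sqrt(acc * (1.0 - acc) / n))


def percent_agreement_and_kappa(labels_a: Sequence, labels_b: Sequence) -> dict:
    """Percent agreement and Cohen's kappa between two binary readings.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    marginal label frequencies.  Perfect agreement returns kappa = 1 even
    when p_e = 1 (single observed category).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty label sequences")
    n = len(a)
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    p_e = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if np.isclose(p_e, 1.0):
        kappa = 1.0 if np.isclose(p_o, 1.0) else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return {"agreement_pct": 100.0 * p_o, "kappa": float(kappa), "n": n}
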