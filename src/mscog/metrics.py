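"""Support-set similarity and diagnostic-accuracy reporting.

Dice similarity compares the predictor sets selected by two sparse models;
the representative member of an ensemble is the one whose support has the
highest mean Dice overlap with all the others. Classification performance is
summarized by sensitivity, specificity, PPV, NPV and balanced accuracy (the
arithmetic mean of sensitivity and specificity), each as a percentage with a
95% Wilson score interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint


def dice(a, b) -> float:
    """Dice similarity ``2|a & b| / (|a| + |b|)`` of two support sets.

    Two empty supports are identical, hence 1; empty vs non-empty is 0.
    """
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def mean_dice_to_others(supports: list[set]) -> np.ndarray:
    """Mean Dice similarity of each support with every other support."""
    n = len(supports)
    if n < 2:
        raise ValueError("need at least 2 supports")
    sims = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims[i, j] = sims[j, i] = dice(supports[i], supports[j])
    return sims.sum(axis=1) / (n - 1)


def select_representative(supports: list[set]) -> tuple[int, np.ndarray]:
    """Index of the support maximizing mean Dice with the others.

    Ties are broken by the lowest index (models are ordered by
    (imputation, fold), so this is the earliest model).
    """
    means = mean_dice_to_others(supports)
    return int(np.argmax(means)), means


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity (same units as inputs)."""
    return (sensitivity + specificity) / 2.0


def proportion_percent(count: int, total: int) -> int:
    """Percentage of a printed count, rounded to the nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def _metric(numerator: int, denominator: int) -> tuple[float, float, float]:
    """Proportion as percent with 95% Wilson CI; NaNs when undefined."""
    if denominator == 0:
        return (math.nan, math.nan, math.nan)
    lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
    return (100.0 * numerator / denominator, 100.0 * lo, 100.0 * hi)


@dataclass
class PerformanceReport:
    """Confusion-matrix metrics (percent) with 95% Wilson intervals."""

    n: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    ppv: tuple[float, float, float]
    npv: tuple[float, float, float]
    balanced_accuracy: float

    def to_dict(self) -> dict:
        def pack(t):
            v, lo, hi = t
            return {"percent": v, "ci_low": lo, "ci_high": hi}

        return {
            "n": self.n,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "sensitivity": pack(self.sensitivity),
            "specificity": pack(self.specificity),
            "ppv": pack(self.ppv),
            "npv": pack(self.npv),
            "balanced_accuracy_percent": self.balanced_accuracy,
        }

    def summary(self) -> str:
        def fmt(name, t):
            v, lo, hi = t
            if math.isnan(v):
                return f"{name:<18} undefined"
            return f"{name:<18} {v:5.1f}% (95% CI {lo:.1f}-{hi:.1f})"

        return "\n".join(
            [
                f"n = {self.n}  (TP {self.tp}, FP {self.fp}, FN {self.fn}, TN {self.tn})",
                f"{'Balanced accuracy':<18} "
                + (
                    f"{self.balanced_accuracy:5.1f}%"
                    if not math.isnan(self.balanced_accuracy)
                    else "undefined"
                ),
                fmt("Sensitivity", self.sensitivity),
                fmt("Specificity", self.specificity),
                fmt("PPV", self.ppv),
                fmt("NPV", self.npv),
            ]
        )


def evaluate_predictions(
    probabilities, labels, threshold: float = 0.5
) -> PerformanceReport:
    """Score predicted probabilities against binary labels at a threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must align")
    if np.isnan(p).any():
        raise ValueError("predictions contain NaN")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    sens = _metric(tp, tp + fn)
    spec = _metric(tn, tn + fp)
    ppv = _metric(tp, tp + fp)
    npv = _metric(tn, tn + fn)
    ba = balanced_accuracy(sens[0], spec[0])
    return PerformanceReport(
        n=len(y), tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        balanced_accuracy=ba,
    )
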