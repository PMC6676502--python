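"""Group-level statistics on per-image background-subtracted intensities.

The central comparison is the fold-change: the ratio of the experimental
group's mean per-image intensity to the control group's.  Dispersion on the
fold is reported as the sample SD of per-image folds (each experimental
image divided by the control mean).  Agreement between two measurement
methods (or two users) on the same images is summarized by ordinary least
squares; staining variability by the coefficient of variation.  All sample
SDs use the n-1 denominator (biological replicates).

Hypothesis testing (t-tests, ANOVA) is deliberately out of scope: results
are exported as CSV for the user's statistics tool of choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    """Summary of one experimental group's per-image values."""

    group_name: str
    per_image_values: list[float]

    @property
    def n(self) -> int:
        return len(self.per_image_values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_image_values))

    @property
    def sd(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(np.std(self.per_image_values, ddof=1))


def fold_change(
    control: GroupSummary, experimental: GroupSummary
) -> tuple[float, float]:
    """Fold-change of the experimental group over controls, with SD.

    fold = experimental.mean / control.mean; the SD is the sample SD of the
    per-image folds (each experimental image value / control mean).
    """
    if control.mean <= 0:
        raise ValueError(
            f"control group mean must be positive for a fold-change, "
            f"got {control.mean}"
        )
    folds = per_image_fold(experimental.per_image_values, control)
    fold = experimental.mean / control.mean
    sd = float(np.std(folds, ddof=1)) if len(folds) >= 2 else float("nan")
    return fold, sd


def per_image_fold(
    images: Sequence[float], control: GroupSummary
) -> list[float]:
    """Each image value divided by the control group mean."""
    if control.mean <= 0:
        raise ValueError("control group mean must be positive")
    return [float(v) / control.mean for v in images]


def agreement(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float, float]:
    """OLS agreement of paired per-image readings: (r_squared, slope, intercept).

    Regresses b on a.  Requires at least 3 pairs and non-constant input.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"paired lists differ in length: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("agreement needs at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("agreement is undefined for constant input")
    res = sps.linregress(a, b)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD (n-1) divided by the mean."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV is undefined for zero mean")
    return float(v.std(ddof=1) / mean)
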