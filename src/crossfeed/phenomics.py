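"""Phenotype quantification for serial-transfer evolution experiments.

Implements the small set of formulas used to score evolved isolates:
secretion fold-changes against a parental baseline, growth rates from
log2-transformed OD curves, generation counts between transfers,
aggregation percentages, background-subtracted biofilm readouts, and the
unpaired two-group t-test used for condition comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GrowthCurve",
    "PlateAssay",
    "fold_change",
    "growth_rate",
    "generations",
    "aggregation_percent",
    "biofilm_readout",
    "two_group_test",
]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series: strictly increasing times (h), positive ODs."""

    times: np.ndarray
    ods: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.ods, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and ods must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a growth curve needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(y > 0):
            raise ValueError("ods must be positive (log transform required)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ods", y)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PlateAssay:
    """Fluorescence screening plate: parental replicates plus isolate wells."""

    parental_values: np.ndarray
    isolate_values: dict[str, np.ndarray]
    blank_value: float | None = None

    def __post_init__(self):
        p = np.asarray(self.parental_values, dtype=float)
        if p.size < 1:
            raise ValueError("need at least one parental replicate")
        if np.any(p < 0):
            raise ValueError("intensities must be non-negative")
        iso = {k: np.asarray(v, dtype=float) for k, v in self.isolate_values.items()}
        for k, v in iso.items():
            if np.any(v < 0):
                raise ValueError(f"negative intensity for isolate {k!r}")
        object.__setattr__(self, "parental_values", p)
        object.__setattr__(self, "isolate_values", iso)

    def log2_fold_changes(self) -> dict[str, float]:
        """log2 fold-change of each isolate mean over the parental mean.

        The parental replicate mean is the sole denominator; a blank is
        subtracted from both sides only if one was recorded.
        """
        blank = self.blank_value or 0.0
        parental = float(np.mean(self.parental_values)) - blank
        out = {}
        for k, v in self.isolate_values.items():
            _, lfc = fold_change(float(np.mean(v)) - blank, parental)
            out[k] = lfc
        return out


def fold_change(isolate_mean: float, parental_mean: float) -> tuple[float, float]:
    """Ratio of an isolate readout to the parental mean, plus its log2.

    Returns ``(ratio, log2_ratio)``. The parental mean must be positive.
    """
    if parental_mean <= 0:
        raise ValueError("parental_mean must be > 0")
    ratio = isolate_mean / parental_mean
    return ratio, math.log2(ratio) if ratio > 0 else -math.inf


def growth_rate(curve: GrowthCurve, min_points: int = 5) -> tuple[float, tuple[int, int]]:
    """Maximum specific growth rate in doublings per hour.

    Fits least-squares lines to log2(OD) over every contiguous window of
    exactly ``min_points`` samples and returns the maximum slope together
    with the ``(start, stop)`` index range of the winning window. Five
    points is the usual choice for monoculture curves; conditioned-media
    curves are typically scored with 6-8.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    n = len(curve)
    if n < min_points:
        raise ValueError(f"curve has {n} points; at least {min_points} required")
    t = curve.times
    y = np.log2(curve.ods)
    best_slope = -np.inf
    best_win = (0, min_points)
    for i in range(n - min_points + 1):
        tw = t[i : i + min_points]
        yw = y[i : i + min_points]
        tc = tw - tw.mean()
        slope = float(np.dot(tc, yw - yw.mean()) / np.dot(tc, tc))
        if slope > best_slope:
            best_slope = slope
            best_win = (i, i + min_points)
    return best_slope, best_win


def generations(a_final: float, a_initial: float) -> float:
    """Generation count between inoculation and transfer.

    Uses the literal formula log10(Af/Ai)/0.3 with the conventional 0.3
    denominator (an approximation of log10(2) that slightly undercounts
    doublings; kept as printed in lab practice).
    """
    if a_final <= 0 or a_initial <= 0:
        raise ValueError("OD values must be positive")
    return math.log10(a_final / a_initial) / 0.3


def aggregation_percent(a_start: float, a_t: float) -> float:
    """Percent sedimentation-driven OD decrease, (1 - At/A0) x 100.

    Negative values (OD above the starting value) are reported as-is.
    """
    if a_start <= 0:
        raise ValueError("starting OD must be positive")
    return (1.0 - a_t / a_start) * 100.0


def biofilm_readout(values, blanks) -> tuple[float, float]:
    """Background-subtracted crystal-violet A570 mean and sample SD.

    The mean of the blank wells is subtracted from every measurement well;
    the SD uses n-1 normalization and is NaN for a single replicate.
    """
    v = np.asarray(values, dtype=float)
    b = np.asarray(blanks, dtype=float)
    if v.size < 1 or b.size < 1:
        raise ValueError("need at least one value and one blank")
    corrected = v - b.mean()
    sd = float(np.std(corrected, ddof=1)) if v.size > 1 else float("nan")
    return float(corrected.mean()), sd


def two_group_test(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed t-test between two condition groups.

    Student's equal-variance form by default; ``welch=True`` drops the
    equal-variance assumption. Two identical zero-variance groups return
    (0.0, 1.0) by convention rather than an undefined statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
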