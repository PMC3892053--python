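"""Percent-improvement transformation and descriptive effect summaries.

Raw endpoint measurements are anchored by two baselines: the healthy
pre-inflammation mean (``t_minus``) and the inflamed pre-treatment mean
(``t_plus``).  Improvement is 0% at the inflamed baseline and 100% on full
return to the healthy baseline; values above 100% are legitimate
(hypoalgesia).  The ordinal lameness score is never run through this
transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError

__all__ = [
    "ENDPOINTS",
    "EffectTimeCourse",
    "ImprovementSeries",
    "EffectSummary",
    "percent_improvement",
    "summarize_effect",
]

ENDPOINTS = (
    "body_temperature",
    "paw_circumference",
    "skin_temperature",
    "creeping_speed",
    "lameness_score",
    "vertical_force",
    "withdrawal_time",
)


@dataclass(frozen=True)
class EffectTimeCourse:
    """One subject x endpoint response series with its two baselines."""

    subject_id: str
    endpoint: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    t_minus: float  # healthy (pre-inflammation) baseline
    t_plus: float  # inflamed (pre-treatment) baseline

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise InputError(f"unknown endpoint {self.endpoint!r}")
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise InputError("times and values must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if self.endpoint == "lameness_score":
            # observed scores are integers; fitted/simulated series are
            # continuous on the same scale, so only the range is enforced
            if np.any((v < 0) | (v > 5)):
                raise InputError("lameness values must lie in [0, 5]")


@dataclass(frozen=True)
class ImprovementSeries:
    """Percent improvement over time; may exceed 100%."""

    times: tuple[float, ...]
    percent: tuple[float, ...]
    endpoint: str


@dataclass(frozen=True)
class EffectSummary:
    max_effect_percent: float
    plateau_start: float
    plateau_end: float
    plateau_duration: float
    total_duration: float
    plateau_undetermined: bool = False


def percent_improvement(course: EffectTimeCourse) -> ImprovementSeries:
    """Elementwise ``(t_plus - M) / (t_plus - t_minus) * 100``.

    The sign convention handles endpoints impaired in either direction
    (fever: ``t_plus > t_minus``; speed: ``t_plus < t_minus``).
    """
    if course.endpoint == "lameness_score":
        raise InputError("lameness_score is summarized on its ordinal scale")
    denom = course.t_plus - course.t_minus
    if denom == 0:
        raise InputError("degenerate baselines: t_plus == t_minus")
    m = np.asarray(course.values, dtype=float)
    pct = (course.t_plus - m) / denom * 100.0
    return ImprovementSeries(
        times=tuple(course.times), percent=tuple(pct), endpoint=course.endpoint
    )


def _threshold_crossing_width(t: np.ndarray, y: np.ndarray, thr: float) -> float:
    """Width of {t : y(t) >= thr} under linear interpolation between samples."""
    above = y >= thr
    if not np.any(above):
        return 0.0
    total = 0.0
    start = None
    for i in range(len(t)):
        if above[i] and start is None:
            if i == 0:
                start = t[0]
            else:
                # interpolate upward crossing in (t[i-1], t[i])
                frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
                start = t[i - 1] + frac * (t[i] - t[i - 1])
        elif not above[i] and start is not None:
            frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
            total += t[i - 1] + frac * (t[i] - t[i - 1]) - start
            start = None
    if start is not None:
        total += t[-1] - start
    return total


def summarize_effect(
    series: ImprovementSeries,
    plateau_tolerance: float = 10.0,
    effect_threshold: float = 10.0,
) -> EffectSummary:
    """Plateau and duration summary of an improvement series.

    The plateau is the longest contiguous observation window whose values
    stay within ``plateau_tolerance`` percentage points of the series
    maximum; the reported maximum effect is the mean over that window.
    Total duration is the width of the region above ``effect_threshold``
    with linear interpolation at the crossings.  A series still rising at
    its last observation has no observable plateau and is flagged
    undetermined.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.percent, dtype=float)
    if len(t) < 3:
        raise InputError("need >= 3 observations to summarize")

    ymax = float(np.max(y))
    if ymax <= 0:
        return EffectSummary(0.0, t[0], t[0], 0.0, 0.0)

    near = y >= ymax - plateau_tolerance
    best_i, best_j = 0, 0  # inclusive window [i, j]
    i = 0
    while i < len(t):
        if near[i]:
            j = i
            while j + 1 < len(t) and near[j + 1]:
                j += 1
            if t[j] - t[i] > t[best_j] - t[best_i]:
                best_i, best_j = i, j
            i = j + 1
        else:
            i += 1

    undetermined = bool(
        np.argmax(y) == len(y) - 1 and len(y) > 1 and np.all(np.diff(y) > 0)
    )
    window = slice(best_i, best_j + 1)
    return EffectSummary(
        max_effect_percent=float(np.mean(y[window])),
        plateau_start=float(t[best_i]),
        plateau_end=float(t[best_j]),
        plateau_duration=float(t[best_j] - t[best_i]),
        total_duration=float(_threshold_crossing_width(t, y, effect_threshold)),
        plateau_undetermined=undetermined,
    )
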