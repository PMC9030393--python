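"""Welding-phase classification and temperature-window intersection.

Phase I is baseline heating below the denaturation onset (default 40 degC),
phase II the denaturation window up to the damage onset (default 60 degC),
phase III thermal damage above it. Thresholds use a half-open-upward
convention: a temperature exactly at a threshold belongs to the higher
phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "Phase",
    "PhaseThresholds",
    "TemperatureRange",
    "PhaseBoundaries",
    "classify_phase",
    "phase_boundaries",
    "intersect_ranges",
]


class Phase(IntEnum):
    I = 1
    II = 2
    III = 3


@dataclass(frozen=True)
class PhaseThresholds:
    denaturation_onset: float = 40.0
    damage_onset: float = 60.0

    def __post_init__(self) -> None:
        if not self.denaturation_onset < self.damage_onset:
            raise ValueError("denaturation onset must be below the damage onset")


@dataclass(frozen=True)
class TemperatureRange:
    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"require low <= high, got [{self.low}, {self.high}]")


@dataclass(frozen=True)
class PhaseBoundaries:
    """First-crossing times (s) of the two thresholds; None when absent."""

    t_denaturation: float | None
    t_damage: float | None


def classify_phase(T: float, thresholds: PhaseThresholds | None = None) -> Phase:
    """Phase of a single temperature (half-open-upward boundaries)."""
    thresholds = thresholds or PhaseThresholds()
    if not np.isfinite(T):
        raise ValueError("temperature must be finite")
    if T < thresholds.denaturation_onset:
        return Phase.I
    if T < thresholds.damage_onset:
        return Phase.II
    return Phase.III


def _first_crossing(times: np.ndarray, temps: np.ndarray, threshold: float) -> float | None:
    if temps[0] >= threshold:
        return float(times[0])
    above = np.nonzero(temps >= threshold)[0]
    if above.size == 0:
        return None
    i = above[0]
    t0, t1 = times[i - 1], times[i]
    y0, y1 = temps[i - 1], temps[i]
    return round(float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0)), 1)


def phase_boundaries(
    times: Sequence[float],
    temps: Sequence[float],
    thresholds: PhaseThresholds | None = None,
) -> PhaseBoundaries:
    """Linear-interpolated first-crossing times of the two thresholds.

    The history is expected to be monotone non-decreasing; a non-monotone
    history triggers a warning and first crossings are still returned.
    Crossing times are reported to 0.1 s.
    """
    thresholds = thresholds or PhaseThresholds()
    times = np.asarray(times, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if times.shape != temps.shape or times.ndim != 1 or times.size < 2:
        raise ValueError("times and temps must be equal-length 1-D with >= 2 points")
    if np.any(np.diff(temps) < -1e-9):
        warnings.warn("temperature history is not monotone non-decreasing", stacklevel=2)
    return PhaseBoundaries(
        t_denaturation=_first_crossing(times, temps, thresholds.denaturation_onset),
        t_damage=_first_crossing(times, temps, thresholds.damage_onset),
    )


def intersect_ranges(ranges: Sequence[TemperatureRange]) -> TemperatureRange | None:
    """Intersection [max of lows, min of highs], or None when empty."""
    if not ranges:
        raise ValueError("at least one range is required")
    low = max(r.low for r in ranges)
    high = min(r.high for r in ranges)
    if low > high:
        return None
    return TemperatureRange(low=low, high=high, label="intersection")
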