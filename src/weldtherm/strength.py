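"""T-peel strength analysis: F-unit normalisation, filtering, group stats.

The F-unit is the peak peel force divided by the weld width (N/mm), making
welds of different footprint sizes comparable. Samples whose weld never
formed or tore ("damaged") are excluded before any statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SampleStatus",
    "StrengthSample",
    "GroupStats",
    "f_unit",
    "peak_force",
    "filter_samples",
    "group_stats",
    "change_rate",
    "read_strength_csv",
    "stats_table",
]

VALID_STATUS = ("ok", "no_weld", "damaged")


@dataclass(frozen=True)
class StrengthSample:
    """One T-peel measurement."""

    sample_id: str
    weld_time_s: float
    peak_force_n: float
    weld_width_mm: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUS:
            raise ValueError(f"status must be one of {VALID_STATUS}, got {self.status!r}")
        if self.peak_force_n < 0:
            raise ValueError("peak force must be >= 0")
        if self.status == "ok" and self.weld_width_mm <= 0:
            raise ValueError("weld width must be > 0 for ok samples")

    @property
    def f_unit(self) -> float:
        return f_unit(self.peak_force_n, self.weld_width_mm)


@dataclass(frozen=True)
class GroupStats:
    group_s: float
    n: int
    max: float
    min: float
    mean: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.min <= self.mean <= self.max:
            raise ValueError("require min <= mean <= max")


def f_unit(force_n: float, width_mm: float) -> float:
    """Strength per unit weld width (N/mm)."""
    if width_mm <= 0:
        raise ValueError(f"weld width must be > 0, got {width_mm}")
    return force_n / width_mm


def peak_force(trace: Union[float, Sequence[float], np.ndarray]) -> float:
    """Peak force from a scalar or a full force-displacement trace."""
    arr = np.atleast_1d(np.asarray(trace, dtype=float))
    if arr.size == 0:
        raise ValueError("empty force trace")
    return float(arr.max())


def filter_samples(
    samples: Iterable[StrengthSample],
) -> tuple[list[StrengthSample], dict[float, int]]:
    """Drop non-ok samples; report the number dropped per time group."""
    kept: list[StrengthSample] = []
    dropped: dict[float, int] = {}
    for s in samples:
        if s.status == "ok":
            kept.append(s)
        else:
            dropped[s.weld_time_s] = dropped.get(s.weld_time_s, 0) + 1
    return kept, dropped


def group_stats(samples: Iterable[StrengthSample]) -> list[GroupStats]:
    """Per-welding-time max/min/mean of the F-unit over ok samples."""
    groups: dict[float, list[float]] = {}
    for s in samples:
        if s.status != "ok":
            continue
        groups.setdefault(s.weld_time_s, []).append(s.f_unit)
    out = []
    for g in sorted(groups):
        vals = np.asarray(groups[g])
        out.append(
            GroupStats(
                group_s=g,
                n=vals.size,
                max=float(vals.max()),
                min=float(vals.min()),
                mean=float(vals.mean()),
            )
        )
    return out


def change_rate(prev_mean: float, curr_mean: float) -> float:
    """Inter-group change of the mean F-unit, in percent."""
    if prev_mean <= 0:
        raise ValueError(f"previous mean must be > 0, got {prev_mean}")
    return 100.0 * (curr_mean / prev_mean - 1.0)


def read_strength_csv(path: Union[str, Path]) -> list[StrengthSample]:
    """Load samples from CSV (sample_id, weld_time_s, peak_force_N, weld_width_mm, status)."""
    df = pd.read_csv(path)
    required = {"sample_id", "weld_time_s", "peak_force_N", "weld_width_mm", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"strength CSV missing columns: {sorted(missing)}")
    return [
        StrengthSample(
            sample_id=str(r.sample_id),
            weld_time_s=float(r.weld_time_s),
            peak_force_n=float(r.peak_force_N),
            weld_width_mm=float(r.weld_width_mm),
            status=str(r.status),
        )
        for r in df.itertuples()
    ]


def stats_table(stats: Sequence[GroupStats]) -> pd.DataFrame:
    """Group statistics plus inter-group change rates, as a DataFrame."""
    rows = []
    prev_mean = None
    for s in stats:
        rate = change_rate(prev_mean, s.mean) if prev_mean else np.nan
        rows.append(
            {
                "weld_time_s": s.group_s,
                "n": s.n,
                "max_n_per_mm": s.max,
                "min_n_per_mm": s.min,
                "mean_n_per_mm": s.mean,
                "change_rate_pct": rate,
            }
        )
        prev_mean = s.mean
    return pd.DataFrame(rows)
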