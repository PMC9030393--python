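"""Infrared-profile analysis: extraction, agreement metric, heat-spread width.

Profiles are temperature vs distance from the electrode edge along the
heat-spread (x) axis at a fixed time. They come either from recorded frames
(pixel grids with a mm/pixel pitch) or from simulated temperature fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ThermalFrame",
    "ThermalProfile",
    "FitReport",
    "UndefinedMetricError",
    "IsothermAbsentError",
    "extract_profile",
    "profile_from_frames",
    "profile_from_simulation",
    "fitting_degree",
    "diffusion_width",
    "deviation_rate",
    "isotherm_z_deviation",
]


class UndefinedMetricError(ValueError):
    """The agreement metric is undefined (constant measured profile)."""


class IsothermAbsentError(ValueError):
    """The requested isotherm does not exist in the field."""


@dataclass(frozen=True)
class ThermalFrame:
    """A single 2-D temperature image (row-major pixels, 0-based indexing)."""

    data: np.ndarray  # (rows, cols) degree C
    pixel_pitch: float  # mm / pixel
    timestamp: float  # s
    frame_rate: float = 30.0  # Hz

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("frame contains non-finite temperatures")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be > 0")


@dataclass(frozen=True)
class ThermalProfile:
    """Temperature vs distance from the electrode edge at one instant."""

    distance_mm: np.ndarray  # non-decreasing
    temperature: np.ndarray  # degree C
    time: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_mm, dtype=float)
        t = np.asarray(self.temperature, dtype=float)
        if d.shape != t.shape or d.ndim != 1:
            raise ValueError("distance and temperature must be equal-length 1-D")
        if np.any(np.diff(d) < 0):
            raise ValueError("distances must be non-decreasing")
        object.__setattr__(self, "distance_mm", d)
        object.__setattr__(self, "temperature", t)

    def __len__(self) -> int:
        return self.distance_mm.size


@dataclass(frozen=True)
class FitReport:
    fitting_degree: float  # percent, <= 100
    window_start_mm: float
    rmse: float  # degree C
    n_points: int
    method: str = "r2"


def profile_from_frames(
    frames: Sequence[ThermalFrame],
    time: float,
    row: int,
    edge_col: int,
    outward: int = +1,
) -> ThermalProfile:
    """Sample a frame row outward from the electrode edge.

    The frame nearest ``time`` is used; distances are measured in mm from
    ``edge_col`` (the pixel column of the electrode edge), increasing in the
    ``outward`` direction (+1 or -1 along columns).
    """
    if not frames:
        raise ValueError("no frames provided")
    stamps = np.array([f.timestamp for f in frames])
    if not stamps.min() - 1e-9 <= time <= stamps.max() + 1e-9:
        raise ValueError(f"time {time} outside the record [{stamps.min()}, {stamps.max()}]")
    frame = frames[int(np.argmin(np.abs(stamps - time)))]
    n_rows, n_cols = frame.data.shape
    if not 0 <= row < n_rows:
        raise ValueError(f"row {row} outside frame with {n_rows} rows")
    if not 0 <= edge_col < n_cols:
        raise ValueError(f"edge column {edge_col} outside frame with {n_cols} columns")
    if outward >= 0:
        cols = np.arange(edge_col, n_cols)
    else:
        cols = np.arange(edge_col, -1, -1)
    distance = np.abs(cols - edge_col) * frame.pixel_pitch
    return ThermalProfile(distance, frame.data[row, cols], time=frame.timestamp)


def profile_from_simulation(result, time: float, y_index: int | None = None) -> ThermalProfile:
    """Edge-area surface profile from a simulation checkpoint.

    Samples the top tissue-surface temperature along +x from the electrode
    edge outward at the given y row (default: slab centre).
    """
    geom = result.geometry
    surface = result.surface_temperature(time)
    iy = geom.ny // 2 if y_index is None else y_index
    if not 0 <= iy < geom.ny:
        raise ValueError(f"y index {iy} outside grid with ny={geom.ny}")
    ix = np.arange(geom.ix_hi, geom.nx)
    distance = (geom.x_centers[ix] - geom.edge_x) * 1e3
    return ThermalProfile(distance, surface[ix, iy], time=time)


def extract_profile(source, time: float, **line) -> ThermalProfile:
    """Dispatch profile extraction over frames or a simulation result."""
    if isinstance(source, (list, tuple)) and source and isinstance(source[0], ThermalFrame):
        return profile_from_frames(source, time, **line)
    return profile_from_simulation(source, time, **line)


def fitting_degree(
    sim: ThermalProfile,
    meas: ThermalProfile,
    window_start: float = 1.0,
    method: str = "r2",
) -> FitReport:
    """Percentage agreement between simulated and measured profiles.

    The simulated profile is linearly interpolated onto the measurement grid
    (the measurement is ground truth), restricted to ``x >= window_start`` mm
    and to the overlap of the two x-ranges. The default metric is the
    coefficient of determination times 100; ``method="nrmse"`` gives
    ``100 * (1 - RMSE/(max-min))`` instead.
    """
    if len(sim) < 3 or len(meas) < 3:
        raise ValueError("profiles need at least 3 points for comparison")
    lo = max(window_start, sim.distance_mm.min(), meas.distance_mm.min())
    hi = min(sim.distance_mm.max(), meas.distance_mm.max())
    sel = (meas.distance_mm >= lo) & (meas.distance_mm <= hi)
    x = meas.distance_mm[sel]
    if x.size < 3:
        raise ValueError("comparison window contains fewer than 3 points")
    y_meas = meas.temperature[sel]
    y_sim = np.interp(x, sim.distance_mm, sim.temperature)
    ss_res = float(np.sum((y_meas - y_sim) ** 2))
    ss_tot = float(np.sum((y_meas - y_meas.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / x.size))
    if method == "r2":
        if ss_tot == 0.0:
            raise UndefinedMetricError("measured profile is constant on the window")
        degree = 100.0 * (1.0 - ss_res / ss_tot)
    elif method == "nrmse":
        span = float(y_meas.max() - y_meas.min())
        if span == 0.0:
            raise UndefinedMetricError("measured profile is constant on the window")
        degree = 100.0 * (1.0 - rmse / span)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FitReport(degree, window_start, rmse, int(x.size), method)


def diffusion_width(
    profile: ThermalProfile, epsilon: float = 0.5, ambient: float = 25.0
) -> float:
    """Width (mm) of the contiguous heated band next to the electrode edge.

    The band extends from the edge (x = 0) as long as ``T - ambient >
    epsilon``; the far end is located by linear interpolation. Returns 0 when
    the excess is nowhere reached at the edge.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = profile.distance_mm
    excess = profile.temperature - ambient - epsilon
    if excess[0] <= 0:
        return 0.0
    below = np.nonzero(excess <= 0)[0]
    if below.size == 0:
        return float(x[-1] - x[0])
    i = below[0]
    x0, x1 = x[i - 1], x[i]
    e0, e1 = excess[i - 1], excess[i]
    return float(x0 + e0 / (e0 - e1) * (x1 - x0) - x[0])


def deviation_rate(isotherm_deviation: float, width: float) -> float:
    """Deviation as a percentage of the thermal-diffusion width."""
    if width <= 0:
        raise ZeroDivisionError("diffusion width must be > 0")
    return 100.0 * isotherm_deviation / width


def _outermost_crossing(x_mm: np.ndarray, temps: np.ndarray, T_iso: float) -> float | None:
    """Outermost x (mm) where a decreasing-outward profile crosses T_iso."""
    above = temps >= T_iso
    if not above.any() or above.all():
        return None
    i = int(np.nonzero(above)[0][-1])
    if i + 1 >= temps.size:
        return float(x_mm[i])
    y0, y1 = temps[i], temps[i + 1]
    return float(x_mm[i] + (y0 - T_iso) / (y0 - y1) * (x_mm[i + 1] - x_mm[i]))


def isotherm_z_deviation(field: np.ndarray, geom, T_iso: float, y_index: int | None = None) -> float:
    """Max spread (mm) of the T_iso isotherm's x-position across the thickness.

    For each tissue z-layer the outermost x where the (centre-y) temperature
    profile crosses ``T_iso`` is located; the result is the spread between the
    top and bottom extremes. A z-uniform field gives 0.
    """
    iy = geom.ny // 2 if y_index is None else y_index
    x_mm = geom.x_centers * 1e3
    positions = []
    for iz in range(geom.nz_electrode, geom.nz_electrode + geom.nz_tissue):
        profile = field[:, iy, iz]
        half = slice(geom.nx // 2, geom.nx)  # positive-x half, decreasing outward
        xc = _outermost_crossing(x_mm[half], profile[half], T_iso)
        if xc is not None:
            positions.append(xc)
    if not positions:
        raise IsothermAbsentError(f"isotherm {T_iso} degC absent from the field")
    return float(max(positions) - min(positions))
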