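"""Coupled electro-thermal time loop.

Each step re-evaluates the temperature-dependent material fields, re-solves
the quasi-static potential, deposits Joule heat and advances the implicit
conduction step. The RF drive is idealised to its RMS-equivalent constant
voltage (``amplitude * sqrt(duty_cycle)``): the thermal time constant is
seconds while the electrical period is micro-seconds, so individual cycles
are never resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .. import materials as mat
from .geometry import GeometryConfig, WeldGeometry, build_geometry
from .potential import PotentialSolver
from .thermal import ThermalSolver

__all__ = [
    "DriveWaveform",
    "SimulationConfig",
    "FieldState",
    "HeatSourceField",
    "SimulationResult",
    "effective_drive",
    "advance_temperature",
    "run_simulation",
]


@dataclass(frozen=True)
class DriveWaveform:
    """Idealised square-wave drive."""

    amplitude: float  # V
    frequency: float = 350e3  # Hz, informational (cycles are not resolved)
    duty_cycle: float = 1.0
    duration: float = 30.0  # s

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must be in (0, 1]")


def effective_drive(w: DriveWaveform) -> float:
    """Thermally equivalent constant (RMS) voltage: ``amplitude * sqrt(duty)``."""
    return w.amplitude * float(np.sqrt(w.duty_cycle))


@dataclass(frozen=True)
class SimulationConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    drive: DriveWaveform = field(default_factory=lambda: DriveWaveform(amplitude=8.5))
    dt: float = 0.05
    end_time: float = 30.0
    initial_tissue_temperature: float = 25.0
    initial_electrode_temperature: float = 20.0
    ambient_temperature: float = 25.0
    h_air: float = 10.0
    h_sink: float = 0.0
    sink_temperature: float = 20.0
    advection_velocity: float = 0.0  # carried for completeness; must stay 0
    perfusion: mat.PerfusionParameters = field(default_factory=mat.PerfusionParameters)
    damage_sigma_cutoff: float | None = None  # degree C; optional sigma collapse
    solver_rtol: float = 1e-6
    checkpoint_times: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.end_time < self.dt:
            raise ValueError("end_time must be >= dt")
        if self.advection_velocity != 0.0:
            raise ValueError("advection velocity must be 0 (ex-vivo, no flow)")


@dataclass
class FieldState:
    """Snapshot of the coupled fields on the full grid."""

    temperature: np.ndarray  # (nx, ny, nz), degree C; NaN on void cells
    potential: np.ndarray  # volts
    sigma: np.ndarray  # S/m
    conductivity: np.ndarray  # W/m/K
    time: float


@dataclass
class HeatSourceField:
    """Volumetric Joule power density per cell (W/m^3, >= 0)."""

    power_density: np.ndarray


def advance_temperature(
    state: FieldState, source: HeatSourceField, dt: float, solver: ThermalSolver
) -> FieldState:
    """One conduction step of a field state (convenience wrapper)."""
    T_active = solver.to_active(state.temperature)
    q_active = solver.to_active(source.power_density)
    T_new = solver.step(T_active, q_active, dt)
    return FieldState(
        temperature=solver.to_full(T_new),
        potential=state.potential,
        sigma=state.sigma,
        conductivity=state.conductivity,
        time=state.time + dt,
    )


@dataclass
class SimulationResult:
    """Recorded history of a coupled run."""

    config: SimulationConfig
    geometry: WeldGeometry
    times: np.ndarray
    central_max: np.ndarray
    central_mean: np.ndarray
    tissue_max: np.ndarray
    checkpoints: dict[float, np.ndarray]  # time -> full temperature field
    energy_input: float
    energy_loss: float
    energy_stored_change: float

    def temperature_at(self, time: float) -> np.ndarray:
        """Checkpoint temperature field nearest the requested time."""
        if not self.checkpoints:
            raise ValueError("run recorded no checkpoints")
        keys = np.array(sorted(self.checkpoints))
        lo, hi = self.times[0], self.times[-1]
        if not lo - 1e-9 <= time <= hi + 1e-9:
            raise ValueError(f"time {time} outside the record [{lo}, {hi}]")
        key = keys[np.argmin(np.abs(keys - time))]
        return self.checkpoints[key]

    def surface_temperature(self, time: float) -> np.ndarray:
        """Top tissue-layer temperature (nx, ny) at the nearest checkpoint."""
        field = self.temperature_at(time)
        iz = self.geometry.nz_electrode + self.geometry.nz_tissue - 1
        return field[:, :, iz]

    def tissue_max_at(self, time: float) -> float:
        """Linearly interpolated maximum tissue temperature at a time."""
        if not self.times[0] - 1e-9 <= time <= self.times[-1] + 1e-9:
            raise ValueError(f"time {time} outside the record")
        return float(np.interp(time, self.times, self.tissue_max))


def run_simulation(
    config: SimulationConfig,
    region_materials: Mapping[str, mat.MaterialProperties] | None = None,
    stop_when: Callable[[float, float], bool] | None = None,
    potential_solver: PotentialSolver | None = None,
) -> SimulationResult:
    """Run the coupled solver and record central-area statistics.

    ``stop_when(t, tissue_max)`` may truncate the run early (used by the
    drive calibration); the recorded history then simply ends sooner.
    ``potential_solver`` allows reusing a factorised solver across runs on
    the same geometry. The run is fully deterministic for a fixed config.
    """
    geom = build_geometry(config.geometry)
    thermal = ThermalSolver(
        geom,
        region_materials=region_materials,
        h_air=config.h_air,
        h_sink=config.h_sink,
        ambient=config.ambient_temperature,
        sink_temperature=config.sink_temperature,
        rtol=config.solver_rtol,
    )
    if potential_solver is not None and potential_solver.geom.shape == geom.shape:
        pot = potential_solver
        pot._last_x = None  # warm starts do not carry across runs
    else:
        pot = PotentialSolver(geom, rtol=config.solver_rtol)

    labels = thermal.cell_labels
    from .geometry import Region

    T = np.where(
        labels == Region.TISSUE,
        config.initial_tissue_temperature,
        config.initial_electrode_temperature,
    ).astype(float)

    central = thermal.to_active(geom.central_mask.astype(float)) > 0.5
    tissue = labels == Region.TISSUE
    v_eff = effective_drive(config.drive)

    n_steps = int(round(config.end_time / config.dt))
    times = [0.0]
    central_max = [float(T[central].max())]
    central_mean = [float(T[central].mean())]
    tissue_max = [float(T[tissue].max())]
    checkpoints: dict[float, np.ndarray] = {}
    remaining_cp = sorted(set(config.checkpoint_times))

    def maybe_checkpoint(t: float) -> None:
        while remaining_cp and t >= remaining_cp[0] - config.dt / 2:
            checkpoints[remaining_cp.pop(0)] = thermal.to_full(T.copy())

    maybe_checkpoint(0.0)
    e_in = 0.0
    e_out = 0.0
    e0 = thermal.stored_energy(T)
    vol = thermal.cell_volumes

    for step in range(1, n_steps + 1):
        t_prev = (step - 1) * config.dt
        sigma = thermal.sigma(T, damage_above=config.damage_sigma_cutoff)
        q = np.zeros(thermal.n)
        if v_eff > 0.0 and t_prev < config.drive.duration:
            V = pot.solve(thermal.to_full(sigma, fill=1.0), v_eff)
            q = thermal.to_active(pot.joule_power(V, thermal.to_full(sigma, fill=1.0)))
        if config.perfusion.enabled:
            q = q + np.where(tissue, mat.perfusion_source(config.perfusion, T), 0.0)
        T = thermal.step(T, q, config.dt)
        t = step * config.dt
        e_in += float(np.sum(q * vol) * config.dt)
        e_out += thermal.last_boundary_loss
        times.append(t)
        central_max.append(float(T[central].max()))
        central_mean.append(float(T[central].mean()))
        tissue_max.append(float(T[tissue].max()))
        maybe_checkpoint(t)
        if stop_when is not None and stop_when(t, tissue_max[-1]):
            break

    return SimulationResult(
        config=config,
        geometry=geom,
        times=np.asarray(times),
        central_max=np.asarray(central_max),
        central_mean=np.asarray(central_mean),
        tissue_max=np.asarray(tissue_max),
        checkpoints=checkpoints,
        energy_input=e_in,
        energy_loss=e_out,
        energy_stored_change=thermal.stored_energy(T) - e0,
    )
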