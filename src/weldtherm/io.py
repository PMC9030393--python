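"""File formats: YAML simulation configs, CSV profiles/spectra/fields, TIFF frames.

All tabular outputs are plain text (two-column or matrix CSV); frame stacks
may additionally be written as single-channel TIFF for IR tooling interop.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .ir import ThermalFrame, ThermalProfile
from .raman import RamanSpectrum
from .solver import DriveWaveform, GeometryConfig, SimulationConfig, SimulationResult
from . import materials as mat

PathLike = Union[str, Path]

__all__ = [
    "load_simulation_config",
    "dump_simulation_config",
    "read_profile_csv",
    "write_profile_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_frame_csv",
    "write_frame_csv",
    "read_frame_tiff_stack",
    "write_frame_tiff_stack",
    "write_simulation_outputs",
]

_MM = 1e-3


def load_simulation_config(source: Union[PathLike, dict]) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from YAML (lengths in mm keys)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)

    g = data.get("geometry", {})
    geometry = GeometryConfig(
        slab_length_x=g.get("slab_length_x_mm", 20.0) * _MM,
        slab_width_y=g.get("slab_width_y_mm", 10.0) * _MM,
        tissue_thickness=g.get("tissue_thickness_mm", 0.958) * _MM,
        electrode_footprint=g.get("electrode_footprint_mm", 3.0) * _MM,
        electrode_thickness=g.get("electrode_thickness_mm", 1.75) * _MM,
        dx=g.get("dx_mm", 0.2) * _MM,
        dy=g.get("dy_mm", 0.2) * _MM,
        dz_target=g.get("dz_mm", 0.12) * _MM,
        dz_electrode_target=g.get("dz_electrode_mm", 0.875) * _MM,
    )
    d = data.get("drive", {})
    drive = DriveWaveform(
        amplitude=d.get("amplitude_v", 8.5),
        frequency=d.get("frequency_hz", 350e3),
        duty_cycle=d.get("duty_cycle", 1.0),
        duration=d.get("duration_s", 30.0),
    )
    t = data.get("thermal", {})
    n = data.get("numerics", {})
    p = data.get("perfusion", {})
    perfusion = mat.PerfusionParameters(
        blood_density=p.get("blood_density", 1050.0),
        blood_heat_capacity=p.get("blood_heat_capacity", 3617.0),
        perfusion_rate=p.get("perfusion_rate", 0.0),
        arterial_temperature=p.get("arterial_temperature_c", 37.0),
        metabolic_source=p.get("metabolic_source", 0.0),
        enabled=p.get("enabled", False),
    )
    return SimulationConfig(
        geometry=geometry,
        drive=drive,
        dt=n.get("dt_s", 0.05),
        end_time=n.get("end_time_s", 30.0),
        initial_tissue_temperature=t.get("initial_tissue_c", 25.0),
        initial_electrode_temperature=t.get("initial_electrode_c", 20.0),
        ambient_temperature=t.get("ambient_c", 25.0),
        h_air=t.get("h_air", 10.0),
        h_sink=t.get("h_sink", 0.0),
        sink_temperature=t.get("sink_temperature_c", 20.0),
        perfusion=perfusion,
        solver_rtol=n.get("solver_rtol", 1e-10),
        checkpoint_times=tuple(n.get("checkpoint_times_s", ())),
        seed=data.get("seed", 0),
    )


def dump_simulation_config(config: SimulationConfig, path: PathLike) -> None:
    g, d = config.geometry, config.drive
    data = {
        "geometry": {
            "slab_length_x_mm": g.slab_length_x / _MM,
            "slab_width_y_mm": g.slab_width_y / _MM,
            "tissue_thickness_mm": g.tissue_thickness / _MM,
            "electrode_footprint_mm": g.electrode_footprint / _MM,
            "electrode_thickness_mm": g.electrode_thickness / _MM,
            "dx_mm": g.dx / _MM,
            "dy_mm": g.dy / _MM,
            "dz_mm": g.dz_target / _MM,
            "dz_electrode_mm": g.dz_electrode_target / _MM,
        },
        "drive": {
            "amplitude_v": d.amplitude,
            "frequency_hz": d.frequency,
            "duty_cycle": d.duty_cycle,
            "duration_s": d.duration,
        },
        "thermal": {
            "initial_tissue_c": config.initial_tissue_temperature,
            "initial_electrode_c": config.initial_electrode_temperature,
            "ambient_c": config.ambient_temperature,
            "h_air": config.h_air,
            "h_sink": config.h_sink,
            "sink_temperature_c": config.sink_temperature,
        },
        "numerics": {
            "dt_s": config.dt,
            "end_time_s": config.end_time,
            "solver_rtol": config.solver_rtol,
            "checkpoint_times_s": list(config.checkpoint_times),
        },
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_profile_csv(path: PathLike) -> ThermalProfile:
    df = pd.read_csv(path)
    if not {"distance_mm", "temperature_C"} <= set(df.columns):
        raise ValueError("profile CSV must have columns distance_mm, temperature_C")
    time = float(df["time_s"].iloc[0]) if "time_s" in df.columns else 0.0
    return ThermalProfile(
        df["distance_mm"].to_numpy(float), df["temperature_C"].to_numpy(float), time=time
    )


def write_profile_csv(profile: ThermalProfile, path: PathLike) -> None:
    pd.DataFrame(
        {
            "distance_mm": profile.distance_mm,
            "temperature_C": profile.temperature,
            "time_s": profile.time,
        }
    ).to_csv(path, index=False)


def read_spectrum_csv(path: PathLike) -> RamanSpectrum:
    df = pd.read_csv(path)
    if not {"wavenumber_cm1", "intensity"} <= set(df.columns):
        raise ValueError("spectrum CSV must have columns wavenumber_cm1, intensity")
    return RamanSpectrum(
        df["wavenumber_cm1"].to_numpy(float), df["intensity"].to_numpy(float)
    )


def write_spectrum_csv(spectrum: RamanSpectrum, path: PathLike) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumber, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def read_frame_csv(path: PathLike, pixel_pitch: float, timestamp: float = 0.0,
                   frame_rate: float = 30.0) -> ThermalFrame:
    data = np.loadtxt(path, delimiter=",")
    return ThermalFrame(np.atleast_2d(data), pixel_pitch, timestamp, frame_rate)


def write_frame_csv(frame: ThermalFrame, path: PathLike) -> None:
    np.savetxt(path, frame.data, delimiter=",", fmt="%.6g")


def read_frame_tiff_stack(path: PathLike, pixel_pitch: float,
                          frame_rate: float = 30.0) -> list[ThermalFrame]:
    import tifffile

    stack = tifffile.imread(path)
    stack = np.atleast_3d(stack)
    if stack.ndim == 2:
        stack = stack[None]
    return [
        ThermalFrame(np.asarray(img, dtype=float), pixel_pitch, i / frame_rate, frame_rate)
        for i, img in enumerate(stack)
    ]


def write_frame_tiff_stack(frames: Sequence[ThermalFrame], path: PathLike) -> None:
    import tifffile

    stack = np.stack([f.data.astype(np.float32) for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")


def write_simulation_outputs(result: SimulationResult, out_dir: PathLike) -> None:
    """Time-series CSV plus one matrix CSV per z-slice per checkpoint."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_s": result.times,
            "central_mean_C": result.central_mean,
            "central_max_C": result.central_max,
            "tissue_max_C": result.tissue_max,
        }
    ).to_csv(out / "timeseries.csv", index=False)
    for t, field in result.checkpoints.items():
        for iz in range(field.shape[2]):
            np.savetxt(
                out / f"T_t{t:g}s_z{iz:02d}.csv",
                field[:, :, iz],
                delimiter=",",
                fmt="%.4f",
            )
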