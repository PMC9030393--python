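"""Synthetic-data generators mirroring the formats the pipeline consumes.

Every generator is a pure function of (config, seed): the same config yields
bit-identical output. Defaults are desk-scaled (96x128 IR frames instead of
the camera's 384x512) so test suites stay fast; the full frame size is one
config field away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import truncnorm

from .ir import ThermalFrame
from .raman import RamanSpectrum, pseudo_voigt
from .strength import StrengthSample

__all__ = [
    "BlobArtifact",
    "IRSyntheticConfig",
    "PeakSpec",
    "RamanSyntheticConfig",
    "StrengthSyntheticConfig",
    "gen_ir_sequence",
    "gen_raman_spectrum",
    "gen_strength_samples",
]


@dataclass(frozen=True)
class BlobArtifact:
    """Localized Gaussian hot/cold blob (emulating e.g. fat residue)."""

    row: float
    col: float
    amplitude: float  # degree C, may be negative
    sigma_px: float = 3.0


@dataclass(frozen=True)
class IRSyntheticConfig:
    frame_rate: float = 30.0
    shape: tuple[int, int] = (96, 128)  # (rows, cols); camera native is (384, 512)
    pixel_pitch: float = 0.1  # mm / pixel
    noise_sd: float = 0.1  # degree C
    n_frames: int = 30
    artifacts: tuple[BlobArtifact, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be > 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def _resample(field: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resample of a 2-D field onto the pixel grid (same extent)."""
    rows, cols = field.shape
    if (rows, cols) == out_shape:
        return np.asarray(field, dtype=float)
    interp = RegularGridInterpolator(
        (np.linspace(0.0, 1.0, rows), np.linspace(0.0, 1.0, cols)),
        np.asarray(field, dtype=float),
    )
    rr = np.linspace(0.0, 1.0, out_shape[0])
    cc = np.linspace(0.0, 1.0, out_shape[1])
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    return interp(grid)


def gen_ir_sequence(
    config: IRSyntheticConfig,
    field: np.ndarray | Callable[[float], np.ndarray],
) -> list[ThermalFrame]:
    """IR frame sequence from a static or time-dependent source field.

    ``field`` is either a 2-D temperature array (static scene) or a callable
    ``t -> 2-D array``. The source field is bilinearly resampled onto the
    configured pixel grid, artifacts are stamped on, and i.i.d. Gaussian
    sensor noise is added. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    artifact_img = np.zeros((rows, cols))
    for blob in config.artifacts:
        artifact_img += blob.amplitude * np.exp(
            -((rr - blob.row) ** 2 + (cc - blob.col) ** 2) / (2.0 * blob.sigma_px**2)
        )
    frames = []
    for i in range(config.n_frames):
        t = i / config.frame_rate
        base = field(t) if callable(field) else field
        img = _resample(base, config.shape) + artifact_img
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        frames.append(
            ThermalFrame(
                data=img,
                pixel_pitch=config.pixel_pitch,
                timestamp=t,
                frame_rate=config.frame_rate,
            )
        )
    return frames


@dataclass(frozen=True)
class PeakSpec:
    center: float  # cm^-1
    height: float
    fwhm: float
    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("FWHM must be > 0")


@dataclass(frozen=True)
class RamanSyntheticConfig:
    peaks: tuple[PeakSpec, ...] = (
        PeakSpec(center=1247.0, height=3000.0, fwhm=40.0, eta=0.5),
        PeakSpec(center=1325.0, height=1400.0, fwhm=60.0, eta=0.5),
    )
    baseline_coeffs: tuple[float, ...] = (0.0,)  # poly in xi = (nu-lo)/(hi-lo)
    wavenumber_lo: float = 800.0
    wavenumber_hi: float = 2000.0
    wavenumber_step: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for p in self.peaks:
            if not self.wavenumber_lo <= p.center <= self.wavenumber_hi:
                raise ValueError(f"peak centre {p.center} outside the grid")


def gen_raman_spectrum(
    config: RamanSyntheticConfig,
) -> tuple[RamanSpectrum, dict]:
    """Pseudo-Voigt peaks + polynomial baseline + Gaussian noise.

    Returns the spectrum and a ground-truth dict with the peak list and the
    evaluated baseline. The baseline polynomial is taken in the normalised
    coordinate ``xi = (nu - lo) / (hi - lo)`` so coefficients stay O(1).
    """
    rng = np.random.default_rng(config.seed)
    nu = np.arange(
        config.wavenumber_lo, config.wavenumber_hi + config.wavenumber_step / 2,
        config.wavenumber_step,
    )
    xi = (nu - config.wavenumber_lo) / (config.wavenumber_hi - config.wavenumber_lo)
    baseline = np.polynomial.polynomial.polyval(xi, np.asarray(config.baseline_coeffs))
    signal = np.zeros_like(nu)
    for p in config.peaks:
        signal = signal + pseudo_voigt(nu, p.height, p.center, p.fwhm, p.eta)
    intensity = signal + baseline
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=nu.shape)
    truth = {"peaks": config.peaks, "baseline": baseline}
    return RamanSpectrum(wavenumber=nu, intensity=intensity), truth


@dataclass(frozen=True)
class StrengthSyntheticConfig:
    group_means: tuple[tuple[float, float], ...] = (
        (10.0, 0.10),
        (15.0, 0.15),
        (20.0, 0.24),
        (25.0, 0.32),
        (30.0, 0.70),
    )  # (weld time s, mean F-unit N/mm)
    group_sds: tuple[float, ...] | float = 0.03
    n_per_group: int = 10
    failure_probability: tuple[float, ...] | float = 0.0
    width_mean_mm: float = 5.0
    width_sd_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        sds = self.group_sds if isinstance(self.group_sds, tuple) else (self.group_sds,)
        if any(sd < 0 for sd in sds):
            raise ValueError("sds must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def _per_group(value, n_groups: int) -> tuple:
    if isinstance(value, tuple):
        if len(value) != n_groups:
            raise ValueError("per-group parameter length mismatch")
        return value
    return (value,) * n_groups


def gen_strength_samples(config: StrengthSyntheticConfig) -> list[StrengthSample]:
    """Per-group F-unit draws from a truncated-at-zero normal.

    Each sample's F-unit is converted to a (force, width) pair through the
    width distribution; a per-group failure probability marks samples as
    damaged (they keep a width but record zero force). Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n_groups = len(config.group_means)
    sds = _per_group(config.group_sds, n_groups)
    fails = _per_group(config.failure_probability, n_groups)
    samples: list[StrengthSample] = []
    for (group, mean), sd, p_fail in zip(config.group_means, sds, fails):
        if sd > 0:
            a = (0.0 - mean) / sd
            funits = truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd, size=config.n_per_group, random_state=rng
            )
        else:
            funits = np.full(config.n_per_group, mean)
        widths = np.clip(
            rng.normal(config.width_mean_mm, config.width_sd_mm, config.n_per_group),
            0.5,
            None,
        )
        failed = rng.random(config.n_per_group) < p_fail
        for i in range(config.n_per_group):
            samples.append(
                StrengthSample(
                    sample_id=f"t{group:g}_s{i}",
                    weld_time_s=group,
                    peak_force_n=0.0 if failed[i] else float(funits[i] * widths[i]),
                    weld_width_mm=float(widths[i]),
                    status="damaged" if failed[i] else "ok",
                )
            )
    return samples
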