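"""Raman workflow: smoothing, baseline removal, windowing, peak calibration.

The band of interest is the amide-III region: the ~1247 cm^-1 collagen peak
is ratioed against the ~1325 cm^-1 elastin/keratin band. Peaks are fitted
with additive pseudo-Voigt (Gauss--Lorentz) profiles sharing one FWHM per
peak between the two components, with a free mixing fraction eta in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

__all__ = [
    "RamanSpectrum",
    "PeakFitResult",
    "BandRatio",
    "FitError",
    "BandAssignmentError",
    "EmptyWindowError",
    "pseudo_voigt",
    "smooth",
    "subtract_baseline",
    "crop",
    "fit_peaks",
    "band_ratio",
    "group_mean_ratio",
]

AMIDE_III_CM1 = 1247.0
REFERENCE_BAND_CM1 = 1325.0
BAND_ASSIGNMENT_WINDOW_CM1 = 40.0


class FitError(RuntimeError):
    """Peak fit failed to converge or the spectrum carries no signal."""


class BandAssignmentError(ValueError):
    """No fitted peak lies within the assignment window of a band."""


class EmptyWindowError(ValueError):
    """Cropping removed every point."""


@dataclass(frozen=True)
class RamanSpectrum:
    """Wavenumber/intensity series with optional sample metadata."""

    wavenumber: np.ndarray  # cm^-1, strictly increasing
    intensity: np.ndarray  # arbitrary units
    sample_id: str | None = None
    weld_time_s: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumber, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if w.shape != y.shape or w.ndim != 1:
            raise ValueError("wavenumber and intensity must be equal-length 1-D")
        if w.size >= 2 and np.any(np.diff(w) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumber", w)
        object.__setattr__(self, "intensity", y)

    def __len__(self) -> int:
        return self.wavenumber.size


@dataclass(frozen=True)
class PeakFitResult:
    """Fitted pseudo-Voigt parameters for one peak."""

    center: float  # cm^-1
    height: float  # a.u. (peak intensity; not area)
    fwhm: float  # cm^-1
    eta: float  # Lorentzian fraction in [0, 1]
    residual: float  # RMS of the joint fit residual

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("FWHM must be > 0")


@dataclass(frozen=True)
class BandRatio:
    """Height ratio of the amide-III band to the reference band."""

    numerator: PeakFitResult
    denominator: PeakFitResult

    @property
    def ratio(self) -> float:
        return self.numerator.height / self.denominator.height


def pseudo_voigt(nu, height: float, center: float, fwhm: float, eta: float):
    """Additive pseudo-Voigt profile with unit-height normalisation.

    ``height * (eta * L + (1 - eta) * G)`` where both components share the
    same centre and FWHM and individually peak at 1.
    """
    x = (np.asarray(nu, dtype=float) - center) / fwhm
    lorentz = 1.0 / (1.0 + 4.0 * x * x)
    gauss = np.exp(-4.0 * np.log(2.0) * x * x)
    return height * (eta * lorentz + (1.0 - eta) * gauss)


def smooth(spectrum: RamanSpectrum, window: int = 11, order: int = 3) -> RamanSpectrum:
    """Savitzky-Golay smoothing (polynomial-window, peak-preserving)."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if order >= window:
        raise ValueError("order must be < window")
    if window > len(spectrum):
        raise ValueError(f"window {window} larger than spectrum ({len(spectrum)} points)")
    y = savgol_filter(spectrum.intensity, window, order)
    return replace(spectrum, intensity=y)


def subtract_baseline(
    spectrum: RamanSpectrum, degree: int = 5, iterations: int = 10
) -> RamanSpectrum:
    """Iteratively re-weighted polynomial baseline removal.

    A degree-``degree`` polynomial is fitted, the working signal clipped to
    the fit (suppressing points above it, i.e. peaks), and the fit repeated;
    the final polynomial is subtracted. Peak-free regions end up near zero.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if degree >= len(spectrum):
        raise ValueError("degree must be smaller than the number of points")
    w = spectrum.wavenumber
    y = spectrum.intensity.astype(float).copy()
    baseline = np.zeros_like(y)
    for _ in range(max(1, iterations)):
        poly = Polynomial.fit(w, y, degree)
        baseline = poly(w)
        y = np.minimum(y, baseline)
    return replace(spectrum, intensity=spectrum.intensity - baseline)


def crop(spectrum: RamanSpectrum, lo: float = 800.0, hi: float = 2000.0) -> RamanSpectrum:
    """Restrict the spectrum to ``lo <= wavenumber <= hi``."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    sel = (spectrum.wavenumber >= lo) & (spectrum.wavenumber <= hi)
    if not sel.any():
        raise EmptyWindowError(f"no points in [{lo}, {hi}] cm^-1")
    return replace(
        spectrum, wavenumber=spectrum.wavenumber[sel], intensity=spectrum.intensity[sel]
    )


def _initial_guess(spectrum: RamanSpectrum, center: float) -> tuple[float, float]:
    w, y = spectrum.wavenumber, spectrum.intensity
    near = np.abs(w - center) <= 25.0
    height = float(y[near].max()) if near.any() else float(y.max())
    return max(height, 1e-12), 40.0


def fit_peaks(
    spectrum: RamanSpectrum,
    initial_centers: Sequence[float],
    center_window: float = 30.0,
    max_fwhm: float = 300.0,
) -> list[PeakFitResult]:
    """Simultaneous least-squares fit of one pseudo-Voigt per initial centre.

    Deterministic for fixed inputs (fixed initialisation, bounded
    parameters). Raises :class:`FitError` when the optimiser fails or the
    spectrum carries no positive signal.
    """
    centers = [float(c) for c in initial_centers]
    if not centers:
        raise ValueError("at least one initial centre is required")
    w = spectrum.wavenumber
    for c in centers:
        if not w.min() <= c <= w.max():
            raise ValueError(f"initial centre {c} outside the spectrum window")
    if not np.any(spectrum.intensity > 0):
        raise FitError("spectrum has no positive signal to fit")

    p0, lower, upper = [], [], []
    for c in centers:
        h0, f0 = _initial_guess(spectrum, c)
        p0 += [h0, c, f0, 0.5]
        lower += [0.0, c - center_window, 1e-3, 0.0]
        upper += [np.inf, c + center_window, max_fwhm, 1.0]

    def model(params):
        out = np.zeros_like(w)
        for i in range(len(centers)):
            h, c, f, eta = params[4 * i : 4 * i + 4]
            out = out + pseudo_voigt(w, h, c, f, eta)
        return out

    result = least_squares(
        lambda p: model(p) - spectrum.intensity,
        x0=np.array(p0),
        bounds=(np.array(lower), np.array(upper)),
        x_scale=np.array([max(abs(v), 1.0) for v in p0]),
    )
    if not result.success:
        raise FitError(
            f"peak fit did not converge (status {result.status}, "
            f"residual {np.sqrt(np.mean(result.fun**2)):g})"
        )
    rms = float(np.sqrt(np.mean(result.fun**2)))
    peaks = []
    for i in range(len(centers)):
        h, c, f, eta = result.x[4 * i : 4 * i + 4]
        peaks.append(
            PeakFitResult(
                center=float(c),
                height=float(h),
                fwhm=float(f),
                eta=float(np.clip(eta, 0.0, 1.0)),
                residual=rms,
            )
        )
    return peaks


def _nearest_peak(
    peaks: Iterable[PeakFitResult], band: float, window: float
) -> PeakFitResult:
    candidates = [p for p in peaks if abs(p.center - band) <= window]
    if not candidates:
        raise BandAssignmentError(
            f"no fitted peak within {window} cm^-1 of the {band:g} cm^-1 band"
        )
    return min(candidates, key=lambda p: abs(p.center - band))


def band_ratio(
    peaks: Sequence[PeakFitResult],
    numerator_band: float = AMIDE_III_CM1,
    denominator_band: float = REFERENCE_BAND_CM1,
    window: float = BAND_ASSIGNMENT_WINDOW_CM1,
) -> BandRatio:
    """Ratio of fitted heights: amide-III band over the reference band."""
    num = _nearest_peak(peaks, numerator_band, window)
    den = _nearest_peak(peaks, denominator_band, window)
    if num is den:
        raise BandAssignmentError("the same peak was assigned to both bands")
    return BandRatio(numerator=num, denominator=den)


def group_mean_ratio(
    grouped_ratios: Mapping[float, Sequence[BandRatio | float]]
) -> dict[float, float]:
    """Arithmetic mean of per-sample band ratios within each time group."""
    means: dict[float, float] = {}
    for group, ratios in grouped_ratios.items():
        values = [r.ratio if isinstance(r, BandRatio) else float(r) for r in ratios]
        if not values:
            raise ValueError(f"group {group!r} has no ratios")
        means[group] = float(np.mean(values))
    return means
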