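"""Emission-spectrum processing: background subtraction, Savitzky-Golay
smoothing, and peak / FWHM / SNR summaries.

Spectra are wavelength–intensity pairs on a uniform grid (nominally 1 nm over
350–700 nm).  The processing chain mirrors standard practice for single-scan
bioluminescence spectra: subtract a background (a measured spectrum when
available, otherwise a constant baseline estimated from the dimmest
channels), smooth once with a second-degree Savitzky–Golay filter over a
25-channel window, then report the peak wavelength at the grid sample, the
full width at half maximum from interpolated half-maximum crossings, and the
signal-to-noise ratio as maximum smoothed intensity over the RMS of the
raw-minus-smoothed residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import savgol_filter

__all__ = [
    "EmissionSpectrum",
    "SpectrumSummary",
    "SpectrumError",
    "NoPeakError",
    "UnboundedWidthError",
    "subtract_background",
    "savitzky_golay",
    "peak_wavelength",
    "fwhm",
    "snr",
    "summarize_spectrum",
]


class SpectrumError(ValueError):
    """Invalid spectrum input or parameters."""


class NoPeakError(SpectrumError):
    """The spectrum has no positive maximum to analyze."""


class UnboundedWidthError(SpectrumError):
    """A half-maximum crossing is missing on one side of the peak."""

    def __init__(self, side: str):
        self.side = side
        super().__init__(f"half-maximum level never crossed on the {side} side")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Wavelength/intensity pairs on a strictly increasing grid.

    ``background``, when present, is a same-grid spectrum measured without
    the sample; ``smoothed_passes`` records how many smoothing passes have
    been applied.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    background: np.ndarray | None = None
    smoothed_passes: int = 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or y.shape != wl.shape:
            raise SpectrumError("wavelengths and intensities must be equal-length 1-D")
        if wl.size < 2:
            raise SpectrumError("spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", y)
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != wl.shape:
                raise SpectrumError("background must be on the identical grid")
            object.__setattr__(self, "background", bg)
        if self.smoothed_passes < 0:
            raise SpectrumError("smoothed_passes must be non-negative")

    def _range_mask(self, window_nm: tuple[float, float] | None) -> np.ndarray:
        if window_nm is None:
            return np.ones(self.wavelengths.size, dtype=bool)
        lo, hi = window_nm
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise SpectrumError("analysis range contains no samples")
        return mask


@dataclass(frozen=True)
class SpectrumSummary:
    """Summary of a processed spectrum, as reported for each measurement."""

    peak_wavelength_nm: float
    fwhm_nm: float
    snr: float
    smoothed_passes: int = 0


def subtract_background(spec: EmissionSpectrum) -> EmissionSpectrum:
    """Subtract the measured background, or a constant dim-channel baseline.

    Without a background vector the baseline is the median of the lowest
    decile of intensities — the dimmest channels of a single-peak spectrum
    sample the instrumental offset.  Negative results are retained (not
    clipped) so residual noise statistics stay unbiased.
    """
    if spec.background is not None:
        corrected = spec.intensities - spec.background
    else:
        n_low = max(1, spec.intensities.size // 10)
        lowest = np.sort(spec.intensities)[:n_low]
        corrected = spec.intensities - float(np.median(lowest))
    return replace(spec, intensities=corrected, background=None)


def _fit_edge(y: np.ndarray, i: int, half: int, degree: int) -> float:
    """Least-squares polynomial fit on the truncated window, evaluated at i."""
    lo = max(0, i - half)
    hi = min(y.size, i + half + 1)
    x = np.arange(lo, hi, dtype=float) - i
    coef = npoly.polyfit(x, y[lo:hi], degree)
    return float(coef[0])


def _sg_pass(y: np.ndarray, window: int, degree: int) -> np.ndarray:
    out = savgol_filter(y, window_length=window, polyorder=degree, mode="interp")
    half = window // 2
    # Replace the edge points with truncated one-sided window fits: no data
    # are invented outside the measured range.
    for i in range(half):
        out[i] = _fit_edge(y, i, half, degree)
    for i in range(y.size - half, y.size):
        out[i] = _fit_edge(y, i, half, degree)
    return out


def savitzky_golay(
    spec: EmissionSpectrum,
    window: int = 25,
    degree: int = 2,
    passes: int = 1,
) -> EmissionSpectrum:
    """Savitzky–Golay least-squares polynomial smoothing.

    Each point is replaced by the value at that point of the degree-``degree``
    polynomial fitted over the centered ``window``-channel range (default: a
    second-degree polynomial over 25 channels, applied once).  Edge points use
    the polynomial fitted on the truncated window.  Polynomials of degree at
    most ``degree`` are reproduced exactly.
    """
    if window % 2 == 0 or window <= degree:
        raise SpectrumError("window must be odd and greater than degree")
    if passes < 0:
        raise SpectrumError("passes must be non-negative")
    if spec.intensities.size < window:
        raise SpectrumError("spectrum shorter than the smoothing window")
    y = spec.intensities
    for _ in range(passes):
        y = _sg_pass(y, window, degree)
    return replace(spec, intensities=y, smoothed_passes=spec.smoothed_passes + passes)


def peak_wavelength(
    spec: EmissionSpectrum, window_nm: tuple[float, float] | None = None
) -> float:
    """Wavelength of the maximal sample (ties broken toward the blue end).

    Reported at the grid sample, matching 1-nm reporting precision.
    """
    mask = spec._range_mask(window_nm)
    y = spec.intensities[mask]
    if np.all(y <= 0):
        raise NoPeakError("spectrum has no positive intensity in range")
    return float(spec.wavelengths[mask][int(np.argmax(y))])


def _cross(wl: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Wavelength where the segment [i, i+1] crosses ``level`` (linear)."""
    y0, y1 = y[i], y[i + 1]
    frac = 0.5 if y1 == y0 else (level - y0) / (y1 - y0)
    return float(wl[i] + frac * (wl[i + 1] - wl[i]))


def fwhm(
    spec: EmissionSpectrum, window_nm: tuple[float, float] | None = None
) -> float:
    """Full width at half maximum: the spectral range at half peak intensity.

    Uses the outermost half-maximum crossings bracketing the global peak —
    the first upward crossing scanning from the blue end and the last
    downward crossing scanning back from the red end — each located by linear
    interpolation.  This makes the width robust to noise ripples near the
    half level.
    """
    mask = spec._range_mask(window_nm)
    wl = spec.wavelengths[mask]
    y = spec.intensities[mask]
    if np.all(y <= 0):
        raise NoPeakError("spectrum has no positive intensity in range")
    peak = int(np.argmax(y))
    half = 0.5 * y[peak]

    left = None
    for i in range(peak):
        if y[i] < half <= y[i + 1]:
            left = _cross(wl, y, i, half)
            break
    if left is None:
        if y[0] >= half:
            raise UnboundedWidthError("left")
        raise UnboundedWidthError("left")

    right = None
    for j in range(y.size - 1, peak, -1):
        if y[j] < half <= y[j - 1]:
            right = _cross(wl, y, j - 1, half)
            break
    if right is None:
        raise UnboundedWidthError("right")
    return right - left


def snr(
    spec_raw: EmissionSpectrum,
    spec_smoothed: EmissionSpectrum,
    window_nm: tuple[float, float] | None = None,
) -> float:
    """Signal-to-noise ratio of a smoothed spectrum.

    Defined as the ratio of the maximum smoothed intensity to the root mean
    square noise over the spectral range, the noise being the raw-minus-
    smoothed residual — the only noise estimate available from a single
    scan.  Identical inputs give ``inf`` (zero residual), not an exception.
    """
    if spec_raw.wavelengths.shape != spec_smoothed.wavelengths.shape or not np.allclose(
        spec_raw.wavelengths, spec_smoothed.wavelengths
    ):
        raise SpectrumError("raw and smoothed spectra must share one grid")
    mask = spec_raw._range_mask(window_nm)
    resid = spec_raw.intensities[mask] - spec_smoothed.intensities[mask]
    rms = math.sqrt(float(np.mean(resid**2)))
    signal = float(np.max(spec_smoothed.intensities[mask]))
    if signal <= 0:
        raise NoPeakError("smoothed spectrum has no positive maximum")
    if rms == 0.0:
        return math.inf
    return signal / rms


def summarize_spectrum(
    spec: EmissionSpectrum,
    window: int = 25,
    degree: int = 2,
    passes: int = 1,
    window_nm: tuple[float, float] | None = None,
) -> SpectrumSummary:
    """Background-subtract, smooth, and summarize one spectrum."""
    corrected = subtract_background(spec)
    smoothed = savitzky_golay(corrected, window=window, degree=degree, passes=passes)
    return SpectrumSummary(
        peak_wavelength_nm=peak_wavelength(smoothed, window_nm),
        fwhm_nm=fwhm(smoothed, window_nm),
        snr=snr(corrected, smoothed, window_nm),
        smoothed_passes=smoothed.smoothed_passes,
    )
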