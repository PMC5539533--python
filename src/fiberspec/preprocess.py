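"""Preprocessing chain: Savitzky–Golay smoothing, per-sample mean spectrum,
and mean-normalization over the 1800–600 cm^-1 fingerprint region.

Default chain (order configurable): mean of technical scans -> smooth
(window 11, order 2) -> restrict to 1800–600 cm^-1 and divide by the region's
mean intensity, so every normalized spectrum has region mean exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import GridError, SampleRecord, Spectrum

__all__ = [
    "PreprocessConfig",
    "savgol_smooth",
    "mean_spectrum",
    "normalize_region",
    "savgol_first_derivative",
    "preprocess_sample",
]


class NonUniformGridError(ValueError):
    """Savitzky–Golay filtering requires an evenly spaced grid."""


class DegenerateSpectrumError(ValueError):
    """Region mean too close to zero to normalize against."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    smooth_window / smooth_polyorder : Savitzky–Golay smoothing filter
        (default 11 points, quadratic).
    deriv_window / deriv_polyorder : Savitzky–Golay first-derivative filter
        used as PCA pretreatment (default 13 points, quadratic).
    norm_region : (high, low) cm^-1 bounds, inclusive, of the region used both
        for restriction and for the mean-normalization constant.
    smooth_before_mean : smooth each scan before averaging instead of
        smoothing the per-sample mean spectrum.
    """

    smooth_window: int = 11
    smooth_polyorder: int = 2
    deriv_window: int = 13
    deriv_polyorder: int = 2
    norm_region: tuple[float, float] = (1800.0, 600.0)
    smooth_before_mean: bool = False

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_polyorder:
            raise ValueError("smooth_window must be odd and > smooth_polyorder")
        if self.deriv_window % 2 == 0 or self.deriv_window <= self.deriv_polyorder:
            raise ValueError("deriv_window must be odd and > deriv_polyorder")
        hi, lo = self.norm_region
        if not hi > lo:
            raise ValueError("norm_region must be (high, low) with high > low")


def _grid_spacing(wavenumbers: np.ndarray, rtol: float = 1e-6) -> float:
    d = np.diff(wavenumbers)
    mean = d.mean()
    if np.abs(d - mean).max() > rtol * abs(mean):
        raise NonUniformGridError("wavenumber grid is not uniform")
    return float(mean)


def savgol_smooth(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Smooth with a local least-squares quadratic (Savitzky–Golay) filter.

    Edge points are handled by fitting the local polynomial on the one-sided
    window (``mode="interp"``), which keeps the 664 cm^-1 region near the grid
    edge usable.
    """
    config = config or PreprocessConfig()
    if len(spectrum) < config.smooth_window:
        raise ValueError(
            f"spectrum of length {len(spectrum)} shorter than window "
            f"{config.smooth_window}"
        )
    _grid_spacing(spectrum.wavenumbers)
    smoothed = savgol_filter(
        spectrum.absorbance,
        window_length=config.smooth_window,
        polyorder=config.smooth_polyorder,
        mode="interp",
    )
    return Spectrum(spectrum.wavenumbers, smoothed)


def mean_spectrum(sample: SampleRecord) -> Spectrum:
    """Pointwise arithmetic mean of a sample's technical scans."""
    stack = np.vstack([s.absorbance for s in sample.scans])
    return Spectrum(sample.grid, stack.mean(axis=0))


def region_mask(wavenumbers: np.ndarray, region: tuple[float, float]) -> np.ndarray:
    hi, lo = region
    return (wavenumbers >= lo) & (wavenumbers <= hi)


def normalize_region(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> Spectrum:
    """Restrict to the normalization region and divide by its mean intensity.

    The mean is the signed arithmetic mean of absorbance over grid points in
    the inclusive region; the output's region mean is 1 up to float rounding.
    """
    config = config or PreprocessConfig()
    mask = region_mask(spectrum.wavenumbers, config.norm_region)
    if mask.sum() < 2:
        raise ValueError(
            f"normalization region {config.norm_region} contains "
            f"{int(mask.sum())} grid points; need >=2"
        )
    values = spectrum.absorbance[mask]
    mean = values.mean()
    if abs(mean) <= 1e-12:
        raise DegenerateSpectrumError(
            "mean intensity in normalization region is ~0; cannot normalize"
        )
    return Spectrum(spectrum.wavenumbers[mask], values / mean)


def savgol_first_derivative(
    matrix: np.ndarray,
    wavenumbers: np.ndarray,
    window: int = 13,
    polyorder: int = 2,
) -> np.ndarray:
    """Row-wise Savitzky–Golay first derivative (per cm^-1) of a spectra
    matrix (samples x variables)."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] < window:
        raise ValueError(f"{matrix.shape[1]} variables < window {window}")
    delta = _grid_spacing(np.asarray(wavenumbers, dtype=float))
    return savgol_filter(
        matrix,
        window_length=window,
        polyorder=polyorder,
        deriv=1,
        delta=delta,
        axis=1,
        mode="interp",
    )


def preprocess_sample(
    sample: SampleRecord, config: PreprocessConfig | None = None
) -> tuple[Spectrum, Spectrum]:
    """Run the per-sample chain.

    Returns ``(smoothed_mean, normalized)``: the smoothed mean spectrum on the
    full grid (used for the 1372/2900 ratio whose 2900 window lies outside the
    normalized region) and its mean-normalized restriction to 1800–600 cm^-1
    (used for every other index and for PCA).
    """
    config = config or PreprocessConfig()
    if config.smooth_before_mean:
        smoothed_scans = [
            savgol_smooth(s, config) for s in sample.scans
        ]
        tmp = SampleRecord(
            sample.sample_id,
            sample.genotype,
            sample.dpa,
            sample.replicate,
            smoothed_scans,
        )
        smoothed = mean_spectrum(tmp)
    else:
        smoothed = savgol_smooth(mean_spectrum(sample), config)
    return smoothed, normalize_region(smoothed, config)
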