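"""Band intensities and the four spectral maturity/crystallinity indices.

Indices computed per sample from preprocessed spectra:

* ``r_value``  — maturity index R = (A1315 - A1800) / (A1236 - A1800); the
  1800 cm^-1 intensity acts as a zero-offset anchor.
* ``ci_ir``    — infrared crystallinity index built from the 708 cm^-1
  (crystalline I-beta) and 730 cm^-1 (amorphous I-alpha) bands with the
  800 cm^-1 intensity as anchor: (A708 - A800) / (A730 - A800).
* ``ratio_1372_2900`` — integrated 1410–1290 over 3000–2800 cm^-1 areas,
  computed from the smoothed (un-normalized) mean spectrum because the
  2900 cm^-1 window lies outside the normalized region; the ratio is
  scale-free so normalization is immaterial.
* ``area_895`` / ``area_664`` — trapezoidal integrals over 910–875 and
  684–650 cm^-1 of the normalized spectra, no local baseline subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import INDEX_COLUMNS, SpectralDataset, Spectrum
from .preprocess import PreprocessConfig, preprocess_sample

__all__ = [
    "BandDefinition",
    "band_intensity",
    "r_value",
    "ci_ir",
    "integrated_intensity",
    "ratio_1372_2900",
    "compute_index_table",
    "R_VALUE_BANDS",
    "CI_IR_BANDS",
    "INTEGRATION_WINDOWS",
]


class DegenerateDenominatorError(ZeroDivisionError):
    """Anchor-offset denominator of a ratio index is ~0."""


@dataclass(frozen=True)
class BandDefinition:
    """A named IR band: nominal center, optional integration window, and the
    direction its intensity moves as the secondary cell wall is deposited."""

    name: str
    center: float
    window: tuple[float, float] | None = None  # (high, low) cm^-1
    direction: str = "anchor"  # increase | decrease | anchor

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease", "anchor"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.window is not None:
            hi, lo = self.window
            if not hi > lo:
                raise ValueError("window must be (high, low) with high > low")


#: Anchor and read bands of the two ratio indices.
R_VALUE_BANDS = {"numerator": 1315.0, "denominator": 1236.0, "anchor": 1800.0}
CI_IR_BANDS = {"numerator": 708.0, "denominator": 730.0, "anchor": 800.0}

#: (high, low) integration windows, cm^-1.
INTEGRATION_WINDOWS = {
    "2900": (3000.0, 2800.0),
    "1372": (1410.0, 1290.0),
    "895": (910.0, 875.0),
    "664": (684.0, 650.0),
}


def band_intensity(spectrum: Spectrum, center: float) -> float:
    """Absorbance at a nominal band position by linear interpolation.

    Centers within one grid spacing outside the span clamp to the edge point:
    the 1800 cm^-1 anchor sits exactly on the normalized-region boundary,
    which after restriction to on-grid points lies a fraction of a spacing
    inside 1800.
    """
    wn = spectrum.wavenumbers
    lo, hi = spectrum.span
    step = (hi - lo) / (len(spectrum) - 1) if len(spectrum) > 1 else 0.0
    if center < lo - step or center > hi + step:
        raise ValueError(
            f"band center {center} cm^-1 outside spectrum span [{lo:.2f}, {hi:.2f}]"
        )
    return float(np.interp(center, wn, spectrum.absorbance))


def _anchored_ratio(
    spectrum: Spectrum, numerator: float, denominator: float, anchor: float
) -> float:
    a_num = band_intensity(spectrum, numerator)
    a_den = band_intensity(spectrum, denominator)
    a_anchor = band_intensity(spectrum, anchor)
    den = a_den - a_anchor
    if abs(den) < 1e-10:
        raise DegenerateDenominatorError(
            f"anchored denominator A{denominator:g} - A{anchor:g} ~ 0"
        )
    return (a_num - a_anchor) / den


def r_value(spectrum: Spectrum, bands: dict | None = None) -> float:
    """Maturity index R = (A1315 - A1800) / (A1236 - A1800)."""
    b = bands or R_VALUE_BANDS
    return _anchored_ratio(spectrum, b["numerator"], b["denominator"], b["anchor"])


def ci_ir(spectrum: Spectrum, bands: dict | None = None) -> float:
    """Crystallinity index CI = (A708 - A800) / (A730 - A800).

    The source protocol names only the three bands and the anchor role of
    800 cm^-1; this crystalline-over-amorphous anchored form mirrors the R
    value's structure and is configurable through ``bands``.
    """
    b = bands or CI_IR_BANDS
    return _anchored_ratio(spectrum, b["numerator"], b["denominator"], b["anchor"])


def integrated_intensity(spectrum: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of absorbance over an inclusive (high, low) window.

    Window endpoints enter through linearly interpolated boundary values; no
    local baseline is subtracted.
    """
    hi, lo = window
    if not hi > lo:
        raise ValueError("window must be (high, low) with high > low")
    smin, smax = spectrum.span
    if lo < smin or hi > smax:
        raise ValueError(
            f"window [{lo}, {hi}] outside spectrum span [{smin:.2f}, {smax:.2f}]"
        )
    wn = spectrum.wavenumbers
    inside = (wn > lo) & (wn < hi)
    xs = np.concatenate(([lo], wn[inside], [hi]))
    ys = np.concatenate(
        (
            [np.interp(lo, wn, spectrum.absorbance)],
            spectrum.absorbance[inside],
            [np.interp(hi, wn, spectrum.absorbance)],
        )
    )
    return float(np.trapezoid(ys, xs))


def ratio_1372_2900(spectrum_full: Spectrum) -> float:
    """Integrated 1372 cm^-1 band area over the 2900 cm^-1 band area.

    Evaluated on the smoothed, un-normalized mean spectrum spanning at least
    650–3000 cm^-1.
    """
    num = integrated_intensity(spectrum_full, INTEGRATION_WINDOWS["1372"])
    den = integrated_intensity(spectrum_full, INTEGRATION_WINDOWS["2900"])
    if den <= 0:
        raise DegenerateDenominatorError("2900 cm^-1 band area <= 0")
    return num / den


def compute_index_table(
    dataset: SpectralDataset, config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Preprocess every sample and compute all five index fields.

    Returns one row per sample in dataset order, columns ``INDEX_COLUMNS``.
    Index errors are re-raised annotated with the offending sample_id.
    """
    config = config or PreprocessConfig()
    rows = []
    for sample in dataset:
        try:
            smoothed, normalized = preprocess_sample(sample, config)
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "genotype": sample.genotype,
                    "dpa": sample.dpa,
                    "r_value": r_value(normalized),
                    "ci_ir": ci_ir(normalized),
                    "ratio_1372_2900": ratio_1372_2900(smoothed),
                    "area_895": integrated_intensity(
                        normalized, INTEGRATION_WINDOWS["895"]
                    ),
                    "area_664": integrated_intensity(
                        normalized, INTEGRATION_WINDOWS["664"]
                    ),
                }
            )
        except (ValueError, ZeroDivisionError) as exc:
            raise type(exc)(f"sample {sample.sample_id!r}: {exc}") from exc
    table = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    if not np.isfinite(table[INDEX_COLUMNS[3:]].to_numpy()).all():
        bad = table.loc[
            ~np.isfinite(table[INDEX_COLUMNS[3:]]).all(axis=1), "sample_id"
        ].tolist()
        raise ValueError(f"non-finite index values for samples {bad}")
    return table
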