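"""Synthetic developing-fiber spectra with the statistical structure the
analysis pipeline assumes.

The study's fiber spectra are not deposited, so every stage is exercised on
generated data: Gaussian bands at the characteristic cell-wall positions,
each interpolating between a primary-wall (young fiber) and a secondary-wall
(mature fiber) amplitude, driven by one or two developmental latents:

* single mode — one cellulose latent ``f = clip((dpa - 10) / 30, 0, 1)``
  drives every band, and cellulose content is affine in ``f``; index-versus-
  cellulose relations are then noise-limited and near-linear by construction.
* realistic mode — a saturating composition latent ``g`` (logistic in DPA,
  midpoint 17 d, scale 3 d) drives the major skeletal C–O/C–C bands while the
  linear maturation latent ``m`` drives the index-bearing bands (1315, 1236,
  895, 708, 730, 1365); cellulose mixes the two (weights 0.25 g + 0.75 m).
  This reproduces the qualitative dissociation seen in real fibers: PC1
  scores plateau after ~24 DPA while the maturity and crystallinity indices
  keep rising to 44 DPA.

Randomness: one root seed; each sample draws from a child stream derived as
``SeedSequence(seed, spawn_key=(sample_index,))`` where ``sample_index`` runs
over genotype x DPA x replicate in config order, so any subset of samples
regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .bands import BandDefinition
from .io import SampleRecord, SpectralDataset, Spectrum

__all__ = [
    "SyntheticBand",
    "SyntheticConfig",
    "load_band_library",
    "default_grid",
    "maturation_latent",
    "composition_latent",
    "cellulose_curve",
    "synth_spectrum",
    "generate_dataset",
]

DEFAULT_DPA = (10, 17, 24, 28, 33, 37, 44)


@dataclass(frozen=True)
class SyntheticBand:
    """One Gaussian band of the generator, with its PCW/SCW amplitudes."""

    name: str
    center: float
    sigma: float
    a_pcw: float
    a_scw: float
    group: str  # composition | maturation
    direction: str

    def amplitude(self, latent: float) -> float:
        return self.a_pcw * (1.0 - latent) + self.a_scw * latent

    def definition(self) -> BandDefinition:
        return BandDefinition(name=self.name, center=self.center, direction=self.direction)


def load_band_library(path=None) -> list[SyntheticBand]:
    """Load the versioned band library (packaged YAML by default)."""
    if path is None:
        text = (
            resources.files("fiberspec").joinpath("data/band_library.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return [SyntheticBand(**b) for b in doc["bands"]]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated experiment: 2 genotypes x 7 harvest DPAs x
    2 biological replicates, >=5 technical scans each, spectra on a
    4000 -> 600 cm^-1 grid at ~1.93 cm^-1 spacing, cellulose rising linearly
    from ~25% at 10 DPA to a 95% plateau at 40 DPA (mature fibers are
    88–96.5% cellulose), 1.5-point assay noise and 0.005-AU spectral noise.
    """

    dpa_list: tuple[int, ...] = DEFAULT_DPA
    genotypes: tuple[str, ...] = ("TM-1", "im")
    replicates: int = 2
    scans_per_sample: int = 5
    grid_high: float = 4000.0
    grid_low: float = 600.0
    grid_step: float = 1.92858
    latent_mode: str = "single"  # single | realistic
    c_min: float = 25.0
    c_max: float = 95.0
    ramp: tuple[float, float] = (10.0, 40.0)
    composition_midpoint: float = 17.0
    composition_scale: float = 3.0
    composition_weight: float = 0.25
    cellulose_noise_sd: float = 1.5
    spectral_noise_sd: float = 0.005
    im_amplitude_deficit: float = 0.0
    seed: int = 42
    band_library: tuple[SyntheticBand, ...] = field(
        default_factory=lambda: tuple(load_band_library())
    )

    def __post_init__(self) -> None:
        if not self.dpa_list:
            raise ValueError("dpa_list is empty")
        if any(d <= 0 for d in self.dpa_list):
            raise ValueError("dpa values must be positive")
        if self.latent_mode not in ("single", "realistic"):
            raise ValueError(f"unknown latent_mode {self.latent_mode!r}")
        if not self.c_min < self.c_max:
            raise ValueError("need c_min < c_max")
        if self.cellulose_noise_sd < 0 or self.spectral_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.im_amplitude_deficit < 1:
            raise ValueError("im_amplitude_deficit must be in [0, 1)")

    def noise_free(self) -> "SyntheticConfig":
        return replace(self, cellulose_noise_sd=0.0, spectral_noise_sd=0.0)


def default_grid(config: SyntheticConfig | None = None) -> np.ndarray:
    """Ascending wavenumber grid covering [grid_low, grid_high] at grid_step,
    anchored at grid_high (instrument convention runs 4000 -> 600)."""
    config = config or SyntheticConfig()
    n = int(np.floor((config.grid_high - config.grid_low) / config.grid_step)) + 1
    descending = config.grid_high - config.grid_step * np.arange(n)
    return descending[::-1].copy()


def maturation_latent(dpa, config: SyntheticConfig | None = None) -> np.ndarray:
    """Linear maturation latent m(d): 0 -> 1 ramp across config.ramp DPA."""
    config = config or SyntheticConfig()
    d0, d1 = config.ramp
    return np.clip((np.asarray(dpa, float) - d0) / (d1 - d0), 0.0, 1.0)


def composition_latent(dpa, config: SyntheticConfig | None = None) -> np.ndarray:
    """Saturating PCW->SCW composition latent g(d): logistic in DPA."""
    config = config or SyntheticConfig()
    z = (np.asarray(dpa, float) - config.composition_midpoint) / config.composition_scale
    return 1.0 / (1.0 + np.exp(-z))


def cellulose_curve(dpa, config: SyntheticConfig | None = None) -> np.ndarray:
    """Noise-free cellulose content (%) at a given DPA.

    Single mode: affine in the maturation latent.  Realistic mode: affine in
    the 0.25/0.75 composition/maturation mixture.
    """
    config = config or SyntheticConfig()
    m = maturation_latent(dpa, config)
    if config.latent_mode == "single":
        latent = m
    else:
        w = config.composition_weight
        latent = w * composition_latent(dpa, config) + (1.0 - w) * m
    return config.c_min + (config.c_max - config.c_min) * latent


def _band_latent(band: SyntheticBand, m: float, g: float, mode: str) -> float:
    if mode == "single":
        return m
    return m if band.group == "maturation" else g


def synth_spectrum(
    dpa: float,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
    amplitude_scale: float = 1.0,
) -> Spectrum:
    """One technical scan at the given developmental age.

    ``amplitude_scale`` multiplies the SCW-driven amplitude gain (used for the
    optional *im* deficit); additive white Gaussian noise at the configured sd.
    """
    config = config or SyntheticConfig()
    grid = default_grid(config)
    m = float(maturation_latent(dpa, config))
    g = float(composition_latent(dpa, config))
    absorbance = np.zeros_like(grid)
    for band in config.band_library:
        latent = _band_latent(band, m, g, config.latent_mode) * amplitude_scale
        amp = band.amplitude(latent)
        absorbance += amp * np.exp(-0.5 * ((grid - band.center) / band.sigma) ** 2)
    if config.spectral_noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when spectral_noise_sd > 0")
        absorbance = absorbance + rng.normal(0.0, config.spectral_noise_sd, grid.size)
    return Spectrum(grid, absorbance)


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[SpectralDataset, pd.Series]:
    """Generate the full factorial dataset and its paired cellulose table.

    Returns ``(dataset, cellulose)`` with
    ``len(dataset) == genotypes x dpa x replicates`` samples of
    ``scans_per_sample`` scans each; cellulose values are the noise-free curve
    plus Gaussian assay noise, clipped to [0, 100].
    """
    config = config or SyntheticConfig()
    samples: list[SampleRecord] = []
    cellulose: dict[str, float] = {}
    index = 0
    for genotype in config.genotypes:
        scale = (
            1.0 - config.im_amplitude_deficit if genotype == "im" else 1.0
        )
        for dpa in config.dpa_list:
            for rep in range(1, config.replicates + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(index,))
                )
                sample_id = f"{genotype}_d{dpa:02d}_r{rep}"
                scans = [
                    synth_spectrum(dpa, config, rng, amplitude_scale=scale)
                    for _ in range(config.scans_per_sample)
                ]
                samples.append(
                    SampleRecord(
                        sample_id=sample_id,
                        genotype=genotype,
                        dpa=int(dpa),
                        replicate=rep,
                        scans=scans,
                    )
                )
                value = float(cellulose_curve(dpa, config))
                if config.cellulose_noise_sd > 0:
                    value += rng.normal(0.0, config.cellulose_noise_sd)
                cellulose[sample_id] = float(np.clip(value, 0.0, 100.0))
                index += 1
    series = pd.Series(cellulose, name="cellulose_pct")
    series.index.name = "sample_id"
    return SpectralDataset(samples), series
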