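import numpy as np
import pytest

from fiberspec import SyntheticConfig, Spectrum, generate_dataset


@pytest.fixture(scope="session")
def fine_grid() -> np.ndarray:
    """Uniform 1 cm^-1 grid spanning the fingerprint + C-H stretch regions."""
    return np.arange(600.0, 3401.0, 1.0)


def gaussian_spectrum(grid, center, sigma, amplitude=1.0) -> Spectrum:
    return Spectrum(grid, amplitude * np.exp(-0.5 * ((grid - center) / sigma) ** 2))


@pytest.fixture(scope="session")
def default_dataset():
    """The default 28-sample synthetic dataset (seed 42), shared read-only."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate_dataset(SyntheticConfig().noise_free())


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """A cut-down design for fast end-to-end tests: 1 genotype, 4 ages,
    2 scans per sample."""
    return SyntheticConfig(
        dpa_list=(10, 24, 37, 44),
        genotypes=("TM-1",),
        replicates=2,
        scans_per_sample=2,
        seed=7,
    )
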