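import numpy as np
import pytest

from aquaspec.core import Spectrum, SpectrumSet, WavenumberGrid
from aquaspec.simulate import (
    ChamberConfig,
    default_grid,
    make_cell_spectrum,
    make_water_spectrum,
    matrigel_reference,
)


@pytest.fixture(scope="session")
def grid() -> WavenumberGrid:
    return default_grid()


@pytest.fixture(scope="session")
def chamber() -> ChamberConfig:
    return ChamberConfig()


@pytest.fixture(scope="session")
def water(grid, chamber) -> Spectrum:
    return make_water_spectrum(grid, chamber)


@pytest.fixture(scope="session")
def matrigel(grid) -> Spectrum:
    return matrigel_reference(grid)


@pytest.fixture(scope="session")
def cell(grid) -> Spectrum:
    return make_cell_spectrum(grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def random_set(grid, rng) -> SpectrumSet:
    """Small random SpectrumSet with metadata, for I/O round trips."""
    spectra = [
        Spectrum(
            grid,
            rng.normal(0.3, 0.1, len(grid)),
            {"id": f"s{i}", "role": "cell", "label": "control", "replicate": i % 2},
        )
        for i in range(4)
    ]
    return SpectrumSet(spectra)
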