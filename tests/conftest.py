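import numpy as np
import pytest

from aquafuzz.preprocessing import TurbidityCalibration
from aquafuzz.spectral_io import Modality, Spectrum, WavelengthGrid
from aquafuzz.synthetic_data import make_reference_library


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def turbidity_cal(grid) -> TurbidityCalibration:
    return TurbidityCalibration(grid=grid)


@pytest.fixture(scope="session")
def library(grid, turbidity_cal):
    """Designated reference spectra built from clean synthetic samples."""
    return make_reference_library(grid=grid, cal=turbidity_cal)


def gaussian_spectrum(grid: WavelengthGrid, center: float, sigma: float,
                      amplitude: float, modality=Modality.FL440,
                      baseline: float = 0.0, **kwargs) -> Spectrum:
    wl = grid.wavelengths()
    values = baseline + amplitude * np.exp(-((wl - center) ** 2) / (2 * sigma ** 2))
    return Spectrum(grid=grid, values=values, modality=modality, **kwargs)
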