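import numpy as np
import pytest

from specal.design import (
    DEFAULT_RANGES,
    LevelMap,
    generate_design,
    realize_concentrations,
    split_runs,
)
from specal.preprocess import select_window
from specal.synthspec import (
    NOISELESS,
    WavelengthGrid,
    default_library,
    simulate_mixtures,
)


@pytest.fixture(scope="session")
def design5():
    return generate_design(5)


@pytest.fixture(scope="session")
def level_map():
    return LevelMap(ranges=dict(DEFAULT_RANGES))


@pytest.fixture(scope="session")
def conc25(design5, level_map):
    return realize_concentrations(design5, level_map)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def library(grid):
    return default_library(seed=0)


@pytest.fixture(scope="session")
def split0(design5):
    return split_runs(design5, n_validation=10, seed=0)


@pytest.fixture(scope="session")
def clean_windowed(conc25, library, grid):
    """Noiseless 25-mixture spectra sliced to the 250-300 nm window."""
    spectra = simulate_mixtures(conc25, library, grid, NOISELESS)
    return select_window(spectra, 250.0, 300.0)


@pytest.fixture(scope="session")
def clean_calval(clean_windowed, conc25, split0):
    """(X_cal, Y_cal, X_val, Y_val) from the noiseless design data."""
    cal, val = split0.calibration_indices, split0.validation_indices
    X = clean_windowed.absorbance
    return X[cal], conc25[cal], X[val], conc25[val]
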