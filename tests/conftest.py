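import numpy as np
import pytest

from lungident import (
    ExcitationSpec,
    FrequencyGrid,
    default_grid,
    default_model,
    solve_frf,
)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def clean_frf(model, grid):
    return solve_frf(model, grid, ExcitationSpec())


@pytest.fixture()
def small_grid():
    return FrequencyGrid(np.linspace(5.0, 150.0, 30))
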