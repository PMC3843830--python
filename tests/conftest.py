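import numpy as np
import pytest

from aviomt import (
    DEFAULT_GRID,
    Spectrum,
    load_reference_table,
    named_average_omt,
    standard_illuminant_d65,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID.copy()


@pytest.fixture(scope="session")
def d65():
    return standard_illuminant_d65(units="photon")


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def uv_omt():
    return named_average_omt("uv")


@pytest.fixture(scope="session")
def v_omt():
    return named_average_omt("v")


def logistic_spectrum(lambda50=350.0, scale=5.0, grid=None, plateau=1.0):
    g = DEFAULT_GRID if grid is None else grid
    vals = plateau / (1.0 + np.exp(-(g - lambda50) / scale))
    return Spectrum(g, vals, kind="transmittance")
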