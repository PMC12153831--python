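import numpy as np
import pandas as pd
import pytest

from fishspat import CpueGrid, SyntheticConfig, generate_env_fields, generate_hauls


def make_grid(values, ncols=None, cell_size=0.1):
    """CpueGrid over a full rectangle of cells carrying the given values.

    ``values`` may be a 2D array (rows = j/latitude, cols = i/longitude) or a
    flat sequence with ``ncols``. Catch equals the value, effort 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values.reshape(-1, ncols)
    nj, ni = values.shape
    jj, ii = np.indices((nj, ni))
    cells = pd.DataFrame(
        {
            "i": ii.ravel() + 1500,  # place near 150°E
            "j": jj.ravel() + 400,   # near 40°N
            "catch_t": values.ravel(),
            "effort_nets": 1.0,
            "cpue": values.ravel(),
        }
    )
    cells["lon_c"] = (cells["i"] + 0.5) * cell_size
    cells["lat_c"] = (cells["j"] + 0.5) * cell_size
    return CpueGrid(cell_size=cell_size, cells=cells)


def sparse_grid(ij_pairs, values, cell_size=0.1):
    """CpueGrid occupying only the given (i, j) cells."""
    ij = np.asarray(ij_pairs)
    values = np.asarray(values, dtype=float)
    cells = pd.DataFrame(
        {
            "i": ij[:, 0],
            "j": ij[:, 1],
            "catch_t": values,
            "effort_nets": 1.0,
            "cpue": values,
        }
    )
    cells["lon_c"] = (cells["i"] + 0.5) * cell_size
    cells["lat_c"] = (cells["j"] + 0.5) * cell_size
    return CpueGrid(cell_size=cell_size, cells=cells)


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic study: 3 years, 400 hauls/year, coarse env grid."""
    return SyntheticConfig(
        years=(2014, 2015, 2016),
        n_hauls_per_year=400,
        env_resolution=0.25,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_fields(small_config):
    return generate_env_fields(small_config)


@pytest.fixture(scope="session")
def small_hauls(small_config, small_fields):
    return generate_hauls(small_config, small_fields)
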