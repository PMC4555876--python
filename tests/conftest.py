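import numpy as np
import pytest

from gridpop.forest import ForestParams
from gridpop.grids import DEFAULT_NODATA, Grid
from gridpop.synthfix import make_landscape


@pytest.fixture(scope="session")
def small_world():
    """A fast 60x60 world with 6 coarse / 24 fine units."""
    return make_landscape(3, n_rows=60, n_cols=60, n_coarse=6,
                          children_per_coarse=4, noise_sd=0.2, smooth_radius=5)


@pytest.fixture(scope="session")
def tiny_params():
    return ForestParams(n_trees=60, seed=7)


def random_binary_grid(rng, n_rows, n_cols, p=0.3, cell_size=100.0):
    values = (rng.random((n_rows, n_cols)) < p).astype(float)
    return Grid(values, cell_size=cell_size)


def random_grid(rng, n_rows, n_cols, nodata_frac=0.0, cell_size=100.0):
    values = rng.normal(size=(n_rows, n_cols)) * 10
    if nodata_frac > 0:
        holes = rng.random((n_rows, n_cols)) < nodata_frac
        values[holes] = DEFAULT_NODATA
    return Grid(values, cell_size=cell_size, nodata=DEFAULT_NODATA)
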