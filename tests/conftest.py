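"""Shared fixtures: synthetic worlds and small deterministic grids.

Session-scoped worlds keep the expensive generation/fit work shared across
tests; everything is seeded so the suite is reproducible.
"""

import warnings

import numpy as np
import pytest

from coralhab import Bathymetry, Grid
from coralhab.synthetic import SyntheticWorldConfig, make_presences, make_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic study region (60 x 80 cells, planted
    temperature-driven niche)."""
    return make_world()


@pytest.fixture(scope="session")
def small_world():
    """Smaller world for cheap end-to-end tests."""
    return make_world(SyntheticWorldConfig(n_rows=36, n_cols=48, seed=11))


@pytest.fixture(scope="session")
def world_presences(world):
    return make_presences(world.stack, world.truth, 300, seed=7)


@pytest.fixture()
def flat_bathy():
    """Flat 12 x 14 seafloor at 1000 m, no land."""
    return Bathymetry(Grid(np.full((12, 14), 1000.0), -10.0, 50.0, 0.1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_background_warning():
    """The small test stacks rarely have 10,000 valid cells; the resulting
    take-all warning is expected."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="requested .* background points"
        )
        yield


def make_grid(values, lon0=0.0, lat0=10.0, cell=0.5, nodata=-9999.0):
    return Grid(np.asarray(values, dtype=float), lon0, lat0, cell, nodata)


@pytest.fixture()
def grid_factory():
    return make_grid
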