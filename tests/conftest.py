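import numpy as np
import pytest

import canopylink as cl


@pytest.fixture(scope="session")
def small_landscape():
    """A 200x200 default-regime landscape shared across module tests."""
    cfg = cl.SimConfig(grid_shape=(200, 200), seed=42)
    return cl.simulate_landscape(cfg)


@pytest.fixture(scope="session")
def default_500_landscape():
    """Default study conditions: 500x500 grid, 35 years."""
    return cl.simulate_landscape(cl.SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_patches(small_landscape):
    return cl.delineate(small_landscape.dmap)


@pytest.fixture(scope="session")
def small_features(small_landscape, small_patches):
    return cl.compute_features(small_patches, small_landscape.dmap)


def random_year_raster(rng, shape=(24, 24), years=(2000, 2001, 2002), p=0.25):
    """Sparse random year-of-disturbance raster for oracle comparisons."""
    grid = np.zeros(shape, dtype=np.uint16)
    mask = rng.random(shape) < p
    grid[mask] = rng.choice(years, size=int(mask.sum()))
    return grid
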