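import numpy as np
import pytest

import sentinet as sn

COST_CHOICES = np.array([0.1, 1.0, 10.0, 100.0, 1000.0])


def random_cost_raster(rng, shape, nodata_frac=0.0, cell_size=300.0):
    grid = rng.choice(COST_CHOICES, size=shape)
    mask = rng.random(shape) < nodata_frac
    if mask.all():
        mask[0, 0] = False
    return sn.CostRaster(grid, nodata_mask=mask, cell_size=cell_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20231025)


@pytest.fixture
def chain3():
    """1x3 unit-cost chain under 4-neighbor resistance averaging."""
    raster = sn.CostRaster(np.ones((1, 3)))
    return sn.build_grid(raster, connectivity=4, averaging="resistance")


@pytest.fixture
def unit_square():
    """2x2 unit-cost grid: a 4-cycle of 1-ohm resistors."""
    raster = sn.CostRaster(np.ones((2, 2)))
    return sn.build_grid(raster, connectivity=4, averaging="resistance")


@pytest.fixture(scope="session")
def small_landscape():
    return sn.generate_landscape(sn.LandscapeSpec(shape=(60, 60), seed=11))


@pytest.fixture(scope="session")
def small_parks(small_landscape):
    return sn.generate_parks(
        sn.ParkSpec(n_parks=15, buffer_radius=450.0, min_spacing=2000.0, seed=12),
        small_landscape,
    )


@pytest.fixture(scope="session")
def fitted(small_landscape, small_parks):
    model = sn.SentinelNetwork.from_parks(small_landscape, small_parks)
    return model.fit()
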