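import numpy as np
import pytest

from oscillayers import GridSpec, ClimateRaster, WorldConfig, make_world


@pytest.fixture(scope="session")
def world():
    """One shared synthetic world (present, lgm, dem, curve)."""
    return make_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def world_config():
    return WorldConfig(seed=7)


@pytest.fixture
def small_spec():
    return GridSpec(ncols=10, nrows=10, xllcorner=0.0, yllcorner=0.0,
                    cellsize=0.5, nodata_value=-9999.0)


def random_raster(spec: GridSpec, seed: int, missing_frac: float = 0.1,
                  variable: str = "bio1") -> ClimateRaster:
    """Random raster with a reproducible missing-cell pattern."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(-50, 50, size=spec.shape)
    if missing_frac > 0:
        holes = rng.random(spec.shape) < missing_frac
        vals[holes] = np.nan
    return ClimateRaster(spec, vals, variable)
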