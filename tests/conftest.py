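import numpy as np
import pytest

from maxscale.grid import CategoricalRaster, Raster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_raster(rng, shape=(12, 15), cell_size=100.0, nodata_frac=0.0,
                  binary=False, origin=(0.0, 0.0)):
    if binary:
        values = (rng.random(shape) < 0.3).astype(float)
    else:
        values = rng.normal(100.0, 25.0, shape)
    mask = rng.random(shape) < nodata_frac
    return Raster(values, cell_size, origin, mask)


def random_categorical(rng, shape=(12, 15), n_classes=13, cell_size=100.0,
                       nodata_frac=0.0):
    legend = {c: f"class_{c}" for c in range(1, n_classes + 1)}
    values = rng.integers(1, n_classes + 1, shape).astype(float)
    mask = rng.random(shape) < nodata_frac
    return CategoricalRaster(values, cell_size, (0.0, 0.0), mask, legend=legend)
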