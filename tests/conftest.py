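import numpy as np
import pytest

from landchange.maps import CategoricalMap, GridTransform


@pytest.fixture
def transform():
    return GridTransform(x_origin=500000.0, y_origin=4000000.0, dx=30.0, dy=30.0)


@pytest.fixture
def make_map(transform):
    """Factory for small categorical maps sharing one grid geometry."""

    def _make(grid, nodata=None, timestamp=None, legend=None, crs="EPSG:32649"):
        grid = np.asarray(grid, dtype=np.int64)
        if legend is None:
            codes = np.unique(grid)
            if nodata is not None:
                codes = codes[codes != nodata]
            legend = {int(c): f"class_{int(c)}" for c in codes}
        return CategoricalMap(
            grid=grid,
            transform=transform,
            legend=legend,
            crs_id=crs,
            nodata_code=nodata,
            timestamp=timestamp,
        )

    return _make


@pytest.fixture
def random_map_pair(make_map):
    """Seeded 6-class random landscape pair on a shared grid."""

    def _make(shape=(50, 50), seed=0, k=6):
        rng = np.random.default_rng(seed)
        m1 = make_map(rng.integers(1, k + 1, size=shape), timestamp=2000.0)
        m2 = make_map(rng.integers(1, k + 1, size=shape), timestamp=2013.0)
        m2.legend = dict(m1.legend)
        return m1, m2

    return _make
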