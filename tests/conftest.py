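import numpy as np
import pytest

from nichespread.raster import RasterGrid
from nichespread.synthetic import make_invasion_fixture, make_virtual_species


def make_template(n_rows=10, n_cols=10, cell_size=0.5, origin_lon=0.0, origin_lat=5.0):
    return RasterGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        cell_size=cell_size,
        values=np.zeros((n_rows, n_cols)),
    )


@pytest.fixture(scope="session")
def virtual_species():
    """Default virtual species shared by read-only tests."""
    return make_virtual_species(seed=1)


@pytest.fixture(scope="session")
def invasion_fixture():
    return make_invasion_fixture(seed=0)


@pytest.fixture
def template():
    return make_template()
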