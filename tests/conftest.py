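import numpy as np
import pytest

from ozotrend.changemap import CLASS_CODES
from ozotrend.geodata import CategoricalRaster, ContinuousRaster, Grid


@pytest.fixture
def small_grid():
    return Grid(origin_x=0.0, origin_y=4000.0, pixel_size=1000.0, n_rows=4, n_cols=4)


@pytest.fixture
def landcover_legend():
    return {code: lab for lab, code in CLASS_CODES.items()}


def make_categorical(codes, nodata=-1, legend=None, pixel_size=1000.0):
    codes = np.asarray(codes, dtype=np.int32)
    grid = Grid(
        origin_x=0.0,
        origin_y=codes.shape[0] * pixel_size,
        pixel_size=pixel_size,
        n_rows=codes.shape[0],
        n_cols=codes.shape[1],
    )
    if legend is None:
        legend = {int(c): str(int(c)) for c in np.unique(codes) if c != nodata}
    return CategoricalRaster(grid, codes, nodata=nodata, legend=legend)


def make_continuous(values, pixel_size=1000.0):
    values = np.asarray(values, dtype=float)
    grid = Grid(
        origin_x=0.0,
        origin_y=values.shape[0] * pixel_size,
        pixel_size=pixel_size,
        n_rows=values.shape[0],
        n_cols=values.shape[1],
    )
    return ContinuousRaster(grid, values)
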