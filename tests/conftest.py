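import numpy as np
import pandas as pd
import pytest

from ecogeo.rasters import RasterGrid
from ecogeo.occurrences import OccurrenceRecord


@pytest.fixture
def gradient_grid():
    """10x10 grid over lon [0,1) x lat (0,1], value = 100*row + col."""
    rows, cols = np.mgrid[0:10, 0:10]
    return RasterGrid(
        name="grad",
        kind="continuous",
        origin=(0.0, 1.0),
        cell_size=0.1,
        nodata=-9999.0,
        values=(100 * rows + cols).astype(float),
    )


def make_grid(values, west=0.0, north=1.0, cell=0.1, nodata=-9999.0,
              kind="continuous", name="g"):
    return RasterGrid(
        name=name, kind=kind, origin=(west, north), cell_size=cell,
        nodata=nodata, values=np.asarray(values, dtype=float),
    )


def make_record(rid, species, lon, lat, lon_text="", lat_text=""):
    return OccurrenceRecord(
        record_id=rid, species=species, longitude=lon, latitude=lat,
        longitude_text=lon_text or repr(lon), latitude_text=lat_text or repr(lat),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
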