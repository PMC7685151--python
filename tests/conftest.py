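import numpy as np
import pytest

from fluxiav.grid import FluxGrid, month_range


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_grid(
    values=None,
    n_years=3,
    start_year=2001,
    lat=(30.0, 34.0, 38.0),
    lon=(-110.0, -105.0, -100.0),
    variable="GPP",
    units="gC m-2 month-1",
    seed=0,
):
    """Small gridded monthly field; random values unless given."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    time = month_range((start_year, 1), n_years * 12)
    if values is None:
        values = np.random.default_rng(seed).normal(
            10.0, 3.0, (len(time), lat.size, lon.size)
        )
    return FluxGrid(
        variable_name=variable,
        values=np.asarray(values, dtype=float),
        time=time,
        lat_centers=lat,
        lon_centers=lon,
        units=units,
    )


@pytest.fixture
def small_grid():
    return make_grid()


@pytest.fixture
def seasonal_series():
    """A grid whose values repeat a fixed 12-month pattern every year."""
    pattern = np.arange(1.0, 13.0)
    n_years = 4
    vals = np.tile(pattern, n_years)[:, None, None] * np.ones((1, 3, 3))
    return make_grid(values=vals, n_years=n_years)
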