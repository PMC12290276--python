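import datetime as dt

import numpy as np
import pytest

from smokescope import make_grid
from smokescope.grid import DailyField
from smokescope.synth import FireEvent, make_scene, simulate_truth


@pytest.fixture(scope="session")
def grid():
    """16 x 10 cell grid at the model's native 0.625 x 0.5 degree spacing."""
    return make_grid(-160.0, 55.0, 0.625, 0.5, 16, 10)


@pytest.fixture(scope="session")
def dates():
    start = dt.date(2019, 5, 1)
    return [start + dt.timedelta(days=k) for k in range(20)]


@pytest.fixture(scope="session")
def one_fire(grid):
    return [
        FireEvent(
            center=grid.cell_center(8, 5),
            start=3,
            duration=10,
            peak_emission=80.0,
            decay_length=1.0,
        )
    ]


@pytest.fixture(scope="session")
def truth(grid, dates, one_fire):
    return simulate_truth(grid, dates, one_fire, seed=7)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default study conditions: biased model, noisy sensors, 40 tracts."""
    return make_scene(n_days=40, seed=11)


def field_like(grid, values, date=dt.date(2019, 6, 1), kind="total"):
    return DailyField(date, np.asarray(values, dtype=float), grid, kind)
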