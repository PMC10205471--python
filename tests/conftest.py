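import numpy as np
import pandas as pd
import pytest

from hgtrade.grids import CountryMask, GriddedField
from hgtrade.health import HealthParams
from hgtrade.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    return generate_world(
        WorldConfig(n_regions=6, n_sectors=3, grid_shape=(18, 36), seed=42)
    )


@pytest.fixture
def world_factory():
    def make(**kwargs):
        defaults = dict(n_regions=5, n_sectors=2, grid_shape=(12, 24), seed=0)
        defaults.update(kwargs)
        return generate_world(WorldConfig(**defaults))

    return make


@pytest.fixture
def health_params():
    """Plain coefficients with unit deflators for hand arithmetic."""
    return HealthParams(
        beta=0.01,
        lambda_=0.25,
        gamma=0.18,
        phi=0.066,
        omega=0.8,
        bw=70.0,
        bw_mode="multiply",
        deflators={2005: 1.0, 2008: 1.0},
    )


def make_field(values, units=""):
    """GriddedField over integer-degree coordinates for toy cases."""
    values = np.asarray(values, dtype=float)
    n_lat, n_lon = values.shape
    return GriddedField(np.arange(n_lat, dtype=float), np.arange(n_lon, dtype=float), values, units)


def single_cell_mask(shape, cells):
    """CountryMask with weight-1 masks: {code: (i, j)} or {code: 2-D weights}."""
    n_lat, n_lon = shape
    weights = {}
    for code, spec in cells.items():
        w = np.zeros(shape)
        if isinstance(spec, tuple):
            w[spec] = 1.0
        else:
            w = np.asarray(spec, dtype=float)
        weights[code] = w
    return CountryMask(np.arange(n_lat, dtype=float), np.arange(n_lon, dtype=float), weights)
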