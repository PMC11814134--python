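import numpy as np
import pytest

from oxispheroid import GridSpec, SimulationConfig, sphere


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_config():
    return SimulationConfig()


@pytest.fixture
def unit_sphere_100():
    """Smooth R = 100 μm sphere at the origin."""
    return sphere((0.0, 0.0, 0.0), 100.0)


def grid_for(model, cells_per_radius, radius):
    return GridSpec.for_model(model, spacing=radius / cells_per_radius, pad_cells=2)
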