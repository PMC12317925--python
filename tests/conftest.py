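import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import catchwalk as cw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def grid_surface():
    """10x10 surface of distinct values, 100 m pixels, origin (0, 1000)."""
    values = np.arange(100, dtype=float).reshape(10, 10)
    return cw.CostSurface(values, resolution=100.0, origin=(0.0, 1000.0))


@pytest.fixture
def random_field():
    """64x64 smooth random cost surface at 10 m resolution."""
    return cw.generate_surface(
        cw.SyntheticSpec("random_field", (64, 64), 10.0, seed=11)
    )
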