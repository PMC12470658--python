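import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ezmap as ez

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_geometry() -> ez.CubeGeometry:
    """The standard 512 x 128 macular cube over 6 x 6 mm."""
    return ez.CubeGeometry()


@pytest.fixture(scope="session")
def small_geometry() -> ez.CubeGeometry:
    """A coarse grid small enough for exhaustive-loop oracles."""
    return ez.CubeGeometry(n_fast=20, n_slow=16)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)


def uniform_map(geometry: ez.CubeGeometry, thickness_um: float) -> ez.EZRPEMap:
    grid = np.full(geometry.shape, float(thickness_um))
    return ez.EZRPEMap(grid, np.ones(geometry.shape, dtype=bool), geometry)


def random_map(geometry: ez.CubeGeometry, rng: np.random.Generator,
               invalid_fraction: float = 0.0) -> ez.EZRPEMap:
    grid = rng.uniform(0.0, 60.0, size=geometry.shape)
    valid = rng.random(geometry.shape) >= invalid_fraction
    if not valid.any():
        valid[0, 0] = True
    return ez.EZRPEMap(grid, valid, geometry)
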