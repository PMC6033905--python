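import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aodfuse.grid import GridSpec
from aodfuse.synthetic import default_scene_config, generate_scene


@pytest.fixture(scope="session")
def small_grid():
    """6 x 6 cell grid, 0.1 degree."""
    return GridSpec(116.0, 116.6, 39.8, 40.4, 0.1)


@pytest.fixture(scope="session")
def small_scene():
    """Seeded 6x6-cell, 120-day scene with cloud+haze dropout (shared)."""
    cfg = default_scene_config(
        n_days=120, seed=7,
        grid=GridSpec(116.0, 116.6, 39.8, 40.4, 0.1),
    )
    return generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
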