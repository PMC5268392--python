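import numpy as np
import pytest
from hypothesis import settings

from socsim import SimulationConfig, World

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_config():
    """A fast world small enough for exhaustive checks."""
    return SimulationConfig(world_size=12.0, n_agents=30, n_rounds=40, seed=7)


@pytest.fixture
def placed_world():
    """A 3-agent world whose positions tests overwrite explicitly."""

    def make(positions, world_size=30.0, radius=1.0, step=1.0, seed=0):
        positions = np.asarray(positions, float)
        cfg = SimulationConfig(
            world_size=world_size,
            n_agents=len(positions),
            n_rounds=0,
            interaction_radius=radius,
            step_length=step,
            seed=seed,
        )
        w = World(cfg)
        w.set_positions(positions)
        return w

    return make
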