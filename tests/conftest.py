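import warnings

import pytest

from navscape.config import ArenaConfig, NavigatorParams
from navscape.density import hex_tessellate
from navscape.simulate import simulate_arena_session

# optimizer chatter from deliberately small fits is not a test signal
warnings.filterwarnings("ignore", message="Maximum Likelihood optimization failed")
warnings.filterwarnings("ignore", message="Inverting hessian failed")
warnings.filterwarnings("ignore", message="overflow encountered")
warnings.filterwarnings("ignore", message="divide by zero encountered")


@pytest.fixture(scope="session")
def short_arena() -> ArenaConfig:
    """One-minute single-block arena session for fast simulations."""
    return ArenaConfig(session_blocks=1, block_duration=60.0)


@pytest.fixture(scope="session")
def grid61():
    """Hex tessellation of the default arena with 61 tiles (4 full rings)."""
    grid = hex_tessellate(5000.0, 700.0, k_neighbors=6)
    assert grid.n == 61
    return grid


@pytest.fixture(scope="session")
def beeline_session(short_arena):
    """A noiseless, unbiased, jitter-free session: straight paths, zero error."""
    nav = NavigatorParams(memory_noise_sd=0.0, thigmotaxis_bias=0.0,
                          idle_prob=0.0, heading_jitter_sd=0.0, seed=123)
    return simulate_arena_session(short_arena, nav)
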