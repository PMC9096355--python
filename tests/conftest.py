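import numpy as np
import pytest

from queencourt import SimConfig, initialize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast little colony for unit tests."""
    return SimConfig(n_workers=12, arena_width=12, arena_height=10, brood_radius=3.0, seed=42)


def make_state_with_positions(queen_xy, worker_xys, arena=(20, 20), **cfg_kwargs):
    """State with hand-placed agents (for geometric observables tests)."""
    cfg = SimConfig(
        n_workers=len(worker_xys),
        arena_width=arena[0],
        arena_height=arena[1],
        brood_radius=4.0,
        seed=0,
        **cfg_kwargs,
    )
    state = initialize(cfg)
    state.x[0], state.y[0] = queen_xy
    for i, (wx, wy) in enumerate(worker_xys, start=1):
        state.x[i], state.y[i] = wx, wy
    return state
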