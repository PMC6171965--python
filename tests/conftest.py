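import numpy as np
import pytest

from astersim import HexagonDomain, SimulationConfig
from astersim.state import SystemState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def domain():
    return HexagonDomain(2.5)


@pytest.fixture
def base_config():
    """Standard parameter set at a small agent count for fast unit tests."""
    return SimulationConfig(n_filaments=10, n_motors=5, seed=7)


def make_state(
    fil=(),
    motors=(),
    n_crosslinkers=0,
):
    """Build a SystemState from per-agent tuples.

    ``fil``: iterable of (x, y, theta) or (x, y, theta, mobile).
    ``motors``: iterable of dicts with optional keys pos, bound (pair of
    filament ids or None), lens (pair), tethered, anchor.
    """
    fil = list(fil)
    motors = list(motors)
    state = SystemState.empty(len(fil), len(motors), n_crosslinkers)
    for i, f in enumerate(fil):
        state.fil_center[i] = f[:2]
        state.fil_angle[i] = f[2]
        if len(f) > 3:
            state.fil_mobile[i] = f[3]
    for j, m in enumerate(motors):
        state.mot_pos[j] = m.get("pos", (0.0, 0.0))
        bound = m.get("bound", (None, None))
        lens = m.get("lens", (0.0, 0.0))
        for h in (0, 1):
            if bound[h] is not None:
                state.mot_bound[j, h] = True
                state.mot_fil[j, h] = bound[h]
                state.mot_len[j, h] = lens[h]
                state.mot_bind_step[j, h] = m.get("bind_steps", (0, 0))[h]
        if m.get("anchor") is not None:
            state.mot_tethered[j] = True
            state.mot_anchor[j] = m["anchor"]
    return state
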