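"""Named experiment presets.

Each preset is a YAML config file plus, where the experiment needs a
patterned initial condition (aligned filaments, a filament bar, tethered
motors, anchored filaments), a state builder applied before the run.
"""

from __future__ import annotations

from importlib import resources


import numpy as np

from ..config import SimulationConfig
from ..geometry import HexagonDomain
from ..patterning import (
    bottom_slice,
    fix_filaments,
    init_aligned,
    init_bar,
    init_random,
    tether_motors,
)
from ..state import SystemState

__all__ = ["available_presets", "load_preset", "build_initial_state"]

#: preset name -> (yaml file, init mode)
_PRESETS: dict[str, tuple[str, str]] = {
    "sparse": ("sparse.yaml", "random"),
    "dense": ("dense.yaml", "random"),
    "dense_high_turnover": ("dense_high_turnover.yaml", "random"),
    "switch_destabilize_attach": ("switch_destabilize_attach.yaml", "random"),
    "switch_destabilize_turnover": ("switch_destabilize_turnover.yaml", "random"),
    "switch_rescue_stiffness": ("switch_rescue_stiffness.yaml", "random"),
    "bar": ("bar.yaml", "bar"),
    "tethered_motors": ("tethered_motors.yaml", "tether"),
    "anchored_filaments": ("anchored_filaments.yaml", "anchor"),
    "crosslinkers_25": ("crosslinkers_25.yaml", "random"),
    "crosslinkers_75": ("crosslinkers_75.yaml", "random"),
    "aligned_crosslinkers": ("aligned_crosslinkers.yaml", "aligned"),
}


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def load_preset(name: str) -> tuple[SimulationConfig, str]:
    """Return (config, init_mode) for a named preset."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset '{name}'; available: {available_presets()}")
    fname, mode = _PRESETS[name]
    with resources.as_file(resources.files(__package__).joinpath(fname)) as path:
        cfg = SimulationConfig.from_yaml(path)
    return cfg, mode


def build_initial_state(
    cfg: SimulationConfig, mode: str, rng: np.random.Generator
) -> SystemState:
    """Construct the initial state for an init mode.

    Modes: ``random``; ``aligned`` (orientations uniform on [0, pi/8]);
    ``bar`` (half the filaments inside a central bar, half straddling,
    turnover-stabilized); ``tether`` (random start, motors in the bottom
    eighth of the domain anchored by one head); ``anchor`` (random
    start, 10% of filaments fixed in the bottom quarter).
    """
    domain = HexagonDomain(cfg.hexagon_circumradius)
    if mode == "random":
        return init_random(cfg, rng)
    if mode == "aligned":
        return init_aligned(cfg, 0.0, np.pi / 8.0, rng)
    if mode == "bar":
        return init_bar(cfg, rng)
    if mode == "tether":
        state = init_random(cfg, rng)
        tether_motors(state, bottom_slice(domain, 1.0 / 8.0))
        return state
    if mode == "anchor":
        state = init_random(cfg, rng)
        fix_filaments(state, 0.1, bottom_slice(domain, 0.25), rng)
        return state
    raise ValueError(f"unknown init mode '{mode}'")
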