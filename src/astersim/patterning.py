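"""Initial conditions and spatial constraints.

Generators for each experimental scenario: fully random networks,
pre-aligned filament fields, a microcontact-printing-style "bar" of
localized filaments, spatially tethered motors, and anchored filament
subsets.  All generators draw from the caller's RNG so that a run is
fully determined by the config seed.  Also home to the mid-run parameter
switch helper used by destabilize/rescue protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig, SwitchEvent
from .geometry import HexagonDomain
from .state import SystemState

__all__ = [
    "Rect",
    "init_random",
    "init_aligned",
    "init_bar",
    "tether_motors",
    "fix_filaments",
    "bottom_slice",
    "apply_switch",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [xmin, xmax] x [ymin, ymax] in um."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("rectangle must have positive extent")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= self.xmin)
            & (p[:, 0] <= self.xmax)
            & (p[:, 1] >= self.ymin)
            & (p[:, 1] <= self.ymax)
        )

    def sample_uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.uniform(self.xmin, self.xmax, n)
        y = rng.uniform(self.ymin, self.ymax, n)
        return np.column_stack([x, y])


def bottom_slice(domain: HexagonDomain, fraction: float) -> Rect:
    """Horizontal slice covering the bottom ``fraction`` of the hexagon's
    bounding box (e.g. 1/8 for the tethered-motor strip, 1/4 for anchored
    filaments)."""
    xmin, xmax, ymin, ymax = domain.bounding_box()
    return Rect(xmin, xmax, ymin, ymin + fraction * (ymax - ymin))


def default_bar(domain: HexagonDomain) -> Rect:
    """Default localization bar: centered, 60% of domain width x 15% of height."""
    xmin, xmax, ymin, ymax = domain.bounding_box()
    w, h = xmax - xmin, ymax - ymin
    cx, cy = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
    return Rect(cx - 0.3 * w, cx + 0.3 * w, cy - 0.075 * h, cy + 0.075 * h)


def _base_state(config: SimulationConfig, rng: np.random.Generator) -> SystemState:
    domain = HexagonDomain(config.hexagon_circumradius)
    state = SystemState.empty(config.n_filaments, config.n_motors, config.n_crosslinkers)
    state.fil_center[:] = domain.sample_uniform(rng, config.n_filaments)
    state.mot_pos[:] = domain.sample_uniform(rng, config.n_motors)
    if config.n_crosslinkers:
        state.xl_pos[:] = domain.sample_uniform(rng, config.n_crosslinkers)
    return state


def init_random(config: SimulationConfig, rng: np.random.Generator) -> SystemState:
    """Fully random initial state: filaments at uniform positions with
    uniform orientations on [0, 2*pi); motors and crosslinkers free at
    uniform positions."""
    state = _base_state(config, rng)
    state.fil_angle[:] = rng.uniform(0.0, 2.0 * np.pi, config.n_filaments)
    return state


def init_aligned(
    config: SimulationConfig,
    angle_lo: float,
    angle_hi: float,
    rng: np.random.Generator,
) -> SystemState:
    """Random positions, orientations uniform on [angle_lo, angle_hi]."""
    if not angle_lo <= angle_hi:
        raise ValueError("require angle_lo <= angle_hi")
    state = _base_state(config, rng)
    state.fil_angle[:] = rng.uniform(angle_lo, angle_hi, config.n_filaments)
    return state


def init_bar(
    config: SimulationConfig,
    rng: np.random.Generator,
    bar_rect: Rect | None = None,
    inside_fraction: float = 0.5,
    immobile: bool = False,
) -> SystemState:
    """Filaments localized to a printed bar; motors over the whole domain.

    ``inside_fraction`` of the filaments lie entirely inside the
    rectangle; the remainder have their minus-end uniform in the
    rectangle and are oriented to place the plus-end outside it.  Bar
    filaments are stabilized (turnover-exempt); set ``immobile`` to also
    pin them in place (the fully immobilized variant).  Either way they
    still bind motors and crosslinkers.
    """
    if not 0.0 <= inside_fraction <= 1.0:
        raise ValueError("inside_fraction must be in [0, 1]")
    domain = HexagonDomain(config.hexagon_circumradius)
    if bar_rect is None:
        bar_rect = default_bar(domain)
    state = _base_state(config, rng)
    n = config.n_filaments
    n_inside = int(round(inside_fraction * n))
    half = 0.5 * config.filament_length

    # wholly inside: center sampled so both ends stay in the rectangle
    inner = Rect(
        bar_rect.xmin + half,
        bar_rect.xmax - half,
        max(bar_rect.ymin + 1e-9, bar_rect.ymin),
        bar_rect.ymax,
    ) if bar_rect.xmax - bar_rect.xmin > config.filament_length else bar_rect
    centers = inner.sample_uniform(rng, n_inside)
    # keep bar filaments horizontal-ish inside a thin bar: draw angles and
    # resample ends until contained (rejection on the orientation)
    angles = rng.uniform(0.0, 2.0 * np.pi, n_inside)
    for _ in range(200):
        u = np.column_stack([np.cos(angles), np.sin(angles)])
        bad = ~(
            bar_rect.contains(centers + half * u) & bar_rect.contains(centers - half * u)
        )
        if not bad.any():
            break
        angles[bad] = rng.uniform(0.0, 2.0 * np.pi, int(bad.sum()))
        centers[bad] = inner.sample_uniform(rng, int(bad.sum()))
    state.fil_center[:n_inside] = centers
    state.fil_angle[:n_inside] = angles

    # straddling: minus-end uniform in the bar, plus-end outside it
    n_out = n - n_inside
    minus = bar_rect.sample_uniform(rng, n_out)
    angles_out = rng.uniform(0.0, 2.0 * np.pi, n_out)
    for _ in range(500):
        u = np.column_stack([np.cos(angles_out), np.sin(angles_out)])
        plus = minus + config.filament_length * u
        bad = bar_rect.contains(plus) | ~domain.contains(plus)
        if not bad.any():
            break
        angles_out[bad] = rng.uniform(0.0, 2.0 * np.pi, int(bad.sum()))
    u = np.column_stack([np.cos(angles_out), np.sin(angles_out)])
    state.fil_center[n_inside:] = minus + half * u
    state.fil_angle[n_inside:] = angles_out

    state.fil_turnover_exempt[:] = True
    if immobile:
        state.fil_mobile[:] = False
    return state


def tether_motors(
    state: SystemState, region: Rect, rng: np.random.Generator | None = None
) -> float:
    """Anchor one head of every motor currently inside ``region``.

    The anchored head is fixed permanently at the motor's current point
    (it never walks or releases); the other head follows normal
    kinetics.  Returns the tethered fraction.
    """
    inside = region.contains(state.mot_pos) & ~state.mot_tethered
    state.mot_tethered[inside] = True
    state.mot_anchor[inside] = state.mot_pos[inside]
    return float(inside.sum() / max(state.n_motors, 1))


def fix_filaments(
    state: SystemState,
    fraction: float,
    region: Rect,
    rng: np.random.Generator,
) -> np.ndarray:
    """Anchor a fraction of filaments inside ``region``.

    The chosen filaments are relocated uniformly into the region,
    flagged immobile and turnover-exempt; they still bind motors and
    crosslinkers.  Returns the anchored filament indices.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_fix = int(round(fraction * state.n_filaments))
    ids = rng.choice(state.n_filaments, size=n_fix, replace=False)
    state.fil_center[ids] = region.sample_uniform(rng, n_fix)
    state.fil_mobile[ids] = False
    state.fil_turnover_exempt[ids] = True
    return ids


def apply_switch(
    config: SimulationConfig, step: int, fieldname: str, value: float
) -> SimulationConfig:
    """Return a config with a parameter switch scheduled at ``step``."""
    schedule = list(config.switch_schedule) + [SwitchEvent(step, fieldname, value)]
    return config.replace(switch_schedule=schedule)
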