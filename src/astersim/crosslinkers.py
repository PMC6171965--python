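"""Passive angle-restricted crosslinkers.

Models the CH-domain bundler class (fimbrin / fascin / alpha-actinin):
a two-point zero-rest-length spring that binds pairs of co-oriented
filaments and resists their separation without walking.  Binding is
polarity-aware — the orientation difference of the two rods, wrapped to
(-pi, pi], must not exceed the angular tolerance (default pi/8), so
anti-parallel filaments are never linked.  Both heads bind atomically at
the mutually closest points of the chosen pair, and the walk
coordinates stay frozen until release.  A bound crosslinker remains
fixed: it releases only when a linked filament turns over or is
re-inserted at the boundary — or, if configured, stochastically or when
stretched past its reach.  Motors pass through bound crosslinkers
unhindered.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .neighbors import grid_candidates
from .segments import point_segment, segment_segment
from .state import NO_FILAMENT, SystemState

__all__ = [
    "angle_difference",
    "crosslinker_search_and_bind",
    "crosslinker_release",
    "release_crosslinkers_on",
    "release_crosslinker_mask",
]


def angle_difference(theta1: np.ndarray, theta2: np.ndarray) -> np.ndarray:
    """Polarity-aware orientation difference, |wrap(theta1 - theta2)| in [0, pi]."""
    d = np.asarray(theta1, float) - np.asarray(theta2, float)
    return np.abs((d + np.pi) % (2.0 * np.pi) - np.pi)


def release_crosslinker_mask(state: SystemState, mask: np.ndarray) -> None:
    """Release the masked crosslinkers; they rejoin the free pool at the
    midpoint of their last head positions."""
    if not mask.any():
        return
    pos = state.xl_head_positions()
    state.xl_pos[mask] = pos[mask].mean(axis=1)
    state.xl_bound[mask] = False
    state.xl_fil[mask] = NO_FILAMENT
    state.xl_len[mask] = 0.0


def release_crosslinkers_on(state: SystemState, fil_ids: np.ndarray) -> None:
    """Release every crosslinker bound to any of the given filaments."""
    if state.n_crosslinkers == 0 or fil_ids.size == 0:
        return
    hit = state.xl_bound & np.isin(state.xl_fil, fil_ids).any(axis=1)
    release_crosslinker_mask(state, hit)


def crosslinker_release(
    state: SystemState, cfg: SimulationConfig, rng: np.random.Generator
) -> None:
    """Optional release channels: over-stretch and stochastic unbinding.

    Both are off by default — a bound crosslinker otherwise stays fixed
    until a linked filament disappears.
    """
    if state.n_crosslinkers == 0:
        return
    sel = state.xl_bound
    if not sel.any():
        return
    drop = np.zeros_like(sel)
    if cfg.crosslinker_break_on_overstretch:
        pos = state.xl_head_positions()
        ext = np.linalg.norm(pos[:, 0, :] - pos[:, 1, :], axis=1)
        drop = sel & (ext > cfg.crosslinker_reach)
    if cfg.crosslinker_unbind_rate > 0:
        p = cfg.step_probability(cfg.crosslinker_unbind_rate)
        stoch = np.zeros_like(sel)
        stoch[sel] = rng.random(int(sel.sum())) < p
        drop |= stoch
    release_crosslinker_mask(state, drop)


def crosslinker_search_and_bind(
    state: SystemState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Diffuse free crosslinkers, then stochastically bind eligible pairs.

    A free crosslinker first takes the same fixed-length isotropic random
    step as a free motor, then — with probability ``attach_rate*dt`` —
    scans filaments within the motor search radius of its position.
    Among all pairs of those candidates that are co-oriented within the
    angular tolerance and whose inter-segment distance is at most the
    crosslinker reach, the closest pair is bound at its mutually closest
    points.
    """
    free = ~state.xl_bound
    n_free = int(free.sum())
    if n_free == 0:
        return
    # diffusion (same step length as free motors)
    ang = rng.uniform(0.0, 2.0 * np.pi, n_free)
    state.xl_pos[free, 0] += cfg.free_motor_diffusion_step * np.cos(ang)
    state.xl_pos[free, 1] += cfg.free_motor_diffusion_step * np.sin(ang)

    p_bind = cfg.step_probability(cfg.xl_attach_rate)
    trial = np.nonzero(free)[0][rng.random(n_free) < p_bind]
    if trial.size == 0:
        return
    half = 0.5 * cfg.filament_length
    centers = state.fil_center
    dirs = state.fil_direction()
    angles = state.fil_angle
    q_idx, f_idx = grid_candidates(state.xl_pos[trial], centers, half + cfg.motor_reach)
    if q_idx.size == 0:
        return
    d, _ = point_segment(state.xl_pos[trial][q_idx], centers[f_idx], dirs[f_idx], half)
    keep = d <= cfg.motor_reach
    q_idx, f_idx = q_idx[keep], f_idx[keep]
    order = np.argsort(q_idx, kind="stable")
    q_idx, f_idx = q_idx[order], f_idx[order]
    uniq, starts, cnts = np.unique(q_idx, return_index=True, return_counts=True)
    for u, lo, n_c in zip(uniq, starts, cnts):
        xl = trial[u]
        cands = np.sort(f_idx[lo : lo + n_c])
        if cands.size < 2:
            continue
        ii, jj = np.triu_indices(cands.size, k=1)
        fi, fj = cands[ii], cands[jj]
        ok = angle_difference(angles[fi], angles[fj]) <= cfg.crosslinker_angle_tol
        if not ok.any():
            continue
        fi, fj = fi[ok], fj[ok]
        dist, s, t = segment_segment(
            centers[fi], dirs[fi], half, centers[fj], dirs[fj], half
        )
        close = dist <= cfg.crosslinker_reach
        if not close.any():
            continue
        pick = np.nonzero(close)[0][np.argmin(dist[close])]
        state.xl_bound[xl] = True
        state.xl_fil[xl] = (fi[pick], fj[pick])
        state.xl_len[xl] = (s[pick], t[pick])
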