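"""Per-timestep physics and the simulation engine.

Model summary
-------------
Rigid polar filaments move in an overdamped viscous medium under the
spring forces of two-headed myosin motors (and passive crosslinkers).
Each step, in fixed order:

1.  fully free motors diffuse (fixed step length, isotropic direction);
2.  free motor heads search within the reach ``r`` and, with
    probability ``p1*dt``, bind a random eligible filament;
3.  free crosslinkers diffuse, search and bind near-parallel filament
    pairs;
4.  bound motor heads walk toward the plus-end at velocity ``v``
    (capped at the tip; arrivals are flagged for release);
5.  spring forces of every connector spanning two attachment points are
    accumulated per filament (force and lever-arm torque) and recorded;
6.  mobile filaments translate and rotate against anisotropic slender-rod
    drag;
7.  heads release: stochastically at ``p0*dt``, flagged plus-end
    arrivals, or (one head) when the end-of-step extension exceeds
    ``r``; over-stretched crosslinkers release both heads;
8.  filaments turn over (whole-rod replacement) at ``p2*dt``, severing
    attachments;
9.  agents that left the hexagon are re-inserted uniformly at random;
10. scheduled parameter switches due this step are applied;
11. scalar series are recorded every step, full snapshots at the
    configured stride.

Forces are computed first and motion follows; release checks use
end-of-step head positions, so a motor stretched past ``r`` by this
step's walk or filament motion exerts one final force (at most
``k*(r + 2 v dt)``) before detaching.  Forces act only while a motor
spans two filaments (or an anchor and a filament); a singly bound motor
simply rides and walks its filament.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .crosslinkers import (
    crosslinker_release,
    crosslinker_search_and_bind,
    release_crosslinkers_on,
)
from .geometry import HexagonDomain
from .neighbors import grid_candidates
from .segments import point_segment
from .state import NO_FILAMENT, SystemState

__all__ = [
    "DragCoefficients",
    "drag_coefficients",
    "motor_force",
    "step_filaments",
    "treadmilling_displacement",
    "accumulate_forces",
    "motor_search_and_bind",
    "motor_walk",
    "motor_release",
    "filament_turnover",
    "enforce_boundary",
    "Engine",
    "FrameSeries",
    "simulate",
]

# Slender-rod end-correction constants for the p -> infinity limit.
GAMMA_PERP = 0.84
GAMMA_PAR = 0.114
GAMMA_ROT = -0.662


@dataclass(frozen=True)
class DragCoefficients:
    """Anisotropic viscous drag on a rigid rod (pN s/um, pN s/um, pN s um)."""

    par: float
    perp: float
    rot: float


def drag_coefficients(
    length: float, diameter: float, viscosity: float
) -> DragCoefficients:
    """Slender-rod drag coefficients for aspect ratio ``p = L/di``.

    ``Gamma_perp = 4 pi eta L / (ln p + 0.84)``,
    ``Gamma_par  = 2 pi eta L / (ln p + 0.114)``,
    ``Gamma_rot  = (1/3) pi eta L^3 / (ln p - 0.662)``,
    natural logarithm throughout.
    """
    if not (length > diameter > 0):
        raise ValueError("require length > diameter > 0")
    if viscosity <= 0:
        raise ValueError("viscosity must be > 0")
    lp = np.log(length / diameter)
    if lp <= -GAMMA_ROT:
        raise ValueError(
            f"aspect ratio too small: ln(L/di) = {lp:.3f} must exceed {-GAMMA_ROT}"
        )
    return DragCoefficients(
        par=2.0 * np.pi * viscosity * length / (lp + GAMMA_PAR),
        perp=4.0 * np.pi * viscosity * length / (lp + GAMMA_PERP),
        rot=np.pi * viscosity * length**3 / (3.0 * (lp + GAMMA_ROT)),
    )


def motor_force(
    head_pos: np.ndarray, other_head_pos: np.ndarray, stiffness: float
) -> np.ndarray:
    """Hookean force on the filament at ``head_pos``: ``k * (other - this)``."""
    return stiffness * (np.asarray(other_head_pos, float) - np.asarray(head_pos, float))


def treadmilling_displacement(
    subunit_rate: float, monomer_size: float, dt: float
) -> float:
    """Per-step displacement a treadmilling filament would make.

    ``subunit_rate * monomer_size * dt`` — the magnitude the model
    justifiably neglects (sub-nanometer per 10 ms step for measured
    subunit exchange rates); documentation/diagnostic utility only,
    never applied to filaments.
    """
    if subunit_rate < 0 or monomer_size < 0 or dt < 0:
        raise ValueError("inputs must be nonnegative")
    return subunit_rate * monomer_size * dt


# ---------------------------------------------------------------------------
# Force accumulation (stage 6)
# ---------------------------------------------------------------------------


@dataclass
class ForceAccumulator:
    """Per-filament summed forces/torques and per-motor force magnitudes."""

    force: np.ndarray           # (N, 2) lab-frame force sum
    torque: np.ndarray          # (N,) sum of len_j * F_perp,j
    motor_force_mag: np.ndarray  # (M,) 0 for motors not spanning two attachments
    elastic_energy: float       # sum over connectors of k ext^2 / 2


def _add_connector_forces(
    acc: ForceAccumulator,
    state: SystemState,
    pos: np.ndarray,      # (n, 2, 2) head positions
    fil: np.ndarray,      # (n, 2) filament index or NO_FILAMENT (anchored head)
    ln: np.ndarray,       # (n, 2) walk coordinates
    stiffness: float,
) -> np.ndarray:
    """Accumulate equal-and-opposite spring forces; returns extension lengths."""
    ext_vec = pos[:, 1, :] - pos[:, 0, :]
    for h, sign in ((0, 1.0), (1, -1.0)):
        on_fil = fil[:, h] >= 0
        f_idx = fil[on_fil, h]
        force = sign * stiffness * ext_vec[on_fil]
        np.add.at(acc.force, f_idx, force)
        theta = state.fil_angle[f_idx]
        f_perp = -force[:, 0] * np.sin(theta) + force[:, 1] * np.cos(theta)
        np.add.at(acc.torque, f_idx, ln[on_fil, h] * f_perp)
    return np.linalg.norm(ext_vec, axis=1)


def accumulate_forces(state: SystemState, cfg: SimulationConfig) -> ForceAccumulator:
    """Sum spring forces of all two-attachment motors and bound crosslinkers."""
    n = state.n_filaments
    acc = ForceAccumulator(
        force=np.zeros((n, 2)),
        torque=np.zeros(n),
        motor_force_mag=np.zeros(state.n_motors),
        elastic_energy=0.0,
    )
    att = state.motor_attached()
    active = att.all(axis=1)
    if active.any():
        pos = state.motor_head_positions()[active]
        fil = np.where(state.mot_bound[active], state.mot_fil[active], NO_FILAMENT)
        ext = _add_connector_forces(
            acc, state, pos, fil, state.mot_len[active], cfg.motor_stiffness
        )
        acc.motor_force_mag[active] = cfg.motor_stiffness * ext
        acc.elastic_energy += 0.5 * cfg.motor_stiffness * float(np.sum(ext**2))
    if state.xl_bound.any():
        sel = state.xl_bound
        pos = state.xl_head_positions()[sel]
        ext = _add_connector_forces(
            acc, state, pos, state.xl_fil[sel], state.xl_len[sel], cfg.xl_stiffness
        )
        acc.elastic_energy += 0.5 * cfg.xl_stiffness * float(np.sum(ext**2))
    return acc


# ---------------------------------------------------------------------------
# Filament motion (stage 7)
# ---------------------------------------------------------------------------


def step_filaments(
    state: SystemState,
    acc: ForceAccumulator,
    drags: DragCoefficients,
    dt: float,
) -> float:
    """Overdamped motion of mobile filaments; returns viscous dissipation.

    Forces are rotated into the filament frame; the center advances by
    ``dt * F_par / Gamma_par`` along the axis and ``dt * F_perp /
    Gamma_perp`` across it, and the angle by ``dt * torque / Gamma_rot``.
    Dissipation is the drag work of the realized displacements,
    ``sum(Gamma_par dpar^2 + Gamma_perp dperp^2 + Gamma_rot dtheta^2)/dt``.
    """
    mob = state.fil_mobile
    if not mob.any():
        return 0.0
    theta = state.fil_angle[mob]
    c, s = np.cos(theta), np.sin(theta)
    fx, fy = acc.force[mob, 0], acc.force[mob, 1]
    f_par = fx * c + fy * s
    f_perp = -fx * s + fy * c
    d_par = dt * f_par / drags.par
    d_perp = dt * f_perp / drags.perp
    d_theta = dt * acc.torque[mob] / drags.rot
    state.fil_center[mob, 0] += d_par * c - d_perp * s
    state.fil_center[mob, 1] += d_par * s + d_perp * c
    state.fil_angle[mob] = theta + d_theta
    diss = (
        drags.par * np.sum(d_par**2)
        + drags.perp * np.sum(d_perp**2)
        + drags.rot * np.sum(d_theta**2)
    ) / dt
    return float(diss)


# ---------------------------------------------------------------------------
# Motor kinetics (stages 1, 2, 4, 5)
# ---------------------------------------------------------------------------


def diffuse_free_motors(
    state: SystemState, cfg: SimulationConfig, rng: np.random.Generator
) -> None:
    """Fixed-length isotropic random step for fully free, untethered motors."""
    att = state.motor_attached()
    free = ~att.any(axis=1) & ~state.mot_tethered
    n = int(free.sum())
    if n == 0:
        return
    ang = rng.uniform(0.0, 2.0 * np.pi, n)
    state.mot_pos[free, 0] += cfg.free_motor_diffusion_step * np.cos(ang)
    state.mot_pos[free, 1] += cfg.free_motor_diffusion_step * np.sin(ang)


def _searching_heads(state: SystemState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Free heads eligible to search this step.

    Returns (motor_idx, head_idx, position).  Both heads of a fully free
    motor search from the motor's point; the lone free head of a
    partially attached motor searches from its partner's position (the
    spring has zero rest length, so the free head sits on the partner).
    """
    att = state.motor_attached()
    pos = state.motor_head_positions()
    mot_idx, head_idx = np.nonzero(~att)
    q = pos[mot_idx, head_idx]
    return mot_idx, head_idx, q


def motor_search_and_bind(
    state: SystemState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    step: int,
) -> None:
    """Stochastic capture of filaments by free motor heads.

    Each free head binds a filament segment within distance ``r`` of its
    search point — deterministically on discovery for the heads of a
    fully free motor when ``free_attach_deterministic`` is set,
    otherwise with probability ``p1*dt``; a one-bound motor's second
    head always binds at ``p1*dt``.  The filament already held by the
    partner head is ineligible, and a fully free motor binding both
    heads in one step takes two distinct filaments.  The candidate among
    the in-range filaments is chosen per ``binding_choice`` (uniformly
    at random, or the nearest); binding sets the walk coordinate to the
    signed along-rod position of the closest point.
    """
    mot_idx, head_idx, q = _searching_heads(state)
    if mot_idx.size == 0:
        return
    p_bind = cfg.step_probability(cfg.motor_attach_rate)
    p_head = np.full(mot_idx.size, p_bind)
    att_any = state.motor_attached().any(axis=1)
    if cfg.free_attach_deterministic:
        # a fully free motor grabs a filament as soon as one is in reach;
        # the attachment rate gates only the second head
        p_head[~att_any[mot_idx]] = 1.0
    trial = rng.random(mot_idx.size) < p_head
    if not trial.any():
        return
    mot_idx, head_idx, q = mot_idx[trial], head_idx[trial], q[trial]

    # one query per searching motor: both heads of a fully free motor share
    # a position (and a candidate set)
    m_uniq, q_first = np.unique(mot_idx, return_index=True)
    half = 0.5 * cfg.filament_length
    reach = half + cfg.motor_reach
    row_rep, fil_cand = grid_candidates(q[q_first], state.fil_center, reach)
    if row_rep.size == 0:
        return
    qm = q[q_first]
    # cheap center-distance prefilter before the exact point-to-segment test
    dvec = qm[row_rep] - state.fil_center[fil_cand]
    close = dvec[:, 0] ** 2 + dvec[:, 1] ** 2 <= reach * reach
    row_rep, fil_cand = row_rep[close], fil_cand[close]
    if row_rep.size == 0:
        return
    dist, t_coord = point_segment(
        qm[row_rep],
        state.fil_center[fil_cand],
        state.fil_direction()[fil_cand],
        half,
    )
    ok = dist <= cfg.motor_reach
    # the partner's filament is ineligible for a one-bound motor's free head
    partner_fil = np.where(
        state.mot_bound[m_uniq, 0], state.mot_fil[m_uniq, 0], state.mot_fil[m_uniq, 1]
    )
    partner_fil = np.where(att_any[m_uniq], partner_fil, NO_FILAMENT)
    ok &= fil_cand != partner_fil[row_rep]
    if not ok.any():
        return
    row_rep, fil_cand, dist, t_coord = row_rep[ok], fil_cand[ok], dist[ok], t_coord[ok]

    nearest = cfg.binding_choice == "nearest"
    if nearest:
        order = np.lexsort((dist, row_rep))  # distance-sorted within groups
    else:
        order = np.argsort(row_rep, kind="stable")  # group only; order free
    row_rep, fil_cand, t_coord = row_rep[order], fil_cand[order], t_coord[order]
    rows, starts, counts = np.unique(row_rep, return_index=True, return_counts=True)

    # heads per searching motor, in ascending (motor, head) order
    _, m_first, m_cnt = np.unique(mot_idx, return_index=True, return_counts=True)
    head1 = head_idx[m_first]          # aligned with m_uniq
    two_heads = m_cnt == 2
    head2 = np.where(two_heads, head_idx[np.minimum(m_first + 1, head_idx.size - 1)], -1)

    # first pick per row (grid emits each filament at most once per query,
    # so every candidate in a group is distinct)
    off1 = np.zeros(rows.size, dtype=np.int64) if nearest else rng.integers(0, counts)
    pick1 = starts + off1
    m_id1 = m_uniq[rows]
    h_id1 = head1[rows]
    state.mot_bound[m_id1, h_id1] = True
    state.mot_fil[m_id1, h_id1] = fil_cand[pick1]
    state.mot_len[m_id1, h_id1] = t_coord[pick1]
    state.mot_bind_step[m_id1, h_id1] = step

    # second head of fully free motors: a distinct filament whose closest
    # point lies within the stretch threshold of the first head's
    # attachment — a motor is never born over-stretched
    sec = np.nonzero(two_heads[rows] & (counts > 1))[0]
    if sec.size:
        dirs = state.fil_direction()
        for g in sec:
            lo, n_c = int(starts[g]), int(counts[g])
            sl = slice(lo, lo + n_c)
            cand_f = fil_cand[sl]
            cand_t = t_coord[sl]
            f1 = fil_cand[pick1[g]]
            pa = (
                state.fil_center[f1]
                + t_coord[pick1[g]] * dirs[f1]
            )
            pb = state.fil_center[cand_f] + cand_t[:, None] * dirs[cand_f]
            ok = (cand_f != f1) & (
                np.linalg.norm(pb - pa, axis=1) <= cfg.motor_reach
            )
            js = np.nonzero(ok)[0]
            if js.size == 0:
                continue
            j = lo + (int(js[0]) if nearest else int(js[rng.integers(0, js.size)]))
            m2, h2 = m_uniq[rows[g]], head2[rows[g]]
            state.mot_bound[m2, h2] = True
            state.mot_fil[m2, h2] = fil_cand[j]
            state.mot_len[m2, h2] = t_coord[j]
            state.mot_bind_step[m2, h2] = step


def motor_walk(state: SystemState, cfg: SimulationConfig) -> np.ndarray:
    """Advance bound heads toward the plus-end; flag heads that reach it.

    Returns an (M, 2) bool mask of heads that arrived at the plus-end
    this step (they release after exerting this step's force).  The walk
    coordinate is capped at +L/2 so a head never sits beyond the tip.
    """
    b = state.mot_bound
    state.mot_len[b] += cfg.motor_velocity * cfg.timestep
    half = 0.5 * cfg.filament_length
    flags = b & (state.mot_len >= half)
    np.clip(state.mot_len, -half, half, out=state.mot_len)
    return flags


def _detach_motor_heads(state: SystemState, mask: np.ndarray, pos: np.ndarray) -> None:
    """Release the masked heads; fully detached motors rejoin the free pool
    at the midpoint of their last head positions."""
    if not mask.any():
        return
    state.mot_bound[mask] = False
    state.mot_fil[mask] = NO_FILAMENT
    state.mot_len[mask] = 0.0
    att = state.motor_attached()
    became_free = ~att.any(axis=1) & ~state.mot_tethered & mask.any(axis=1)
    state.mot_pos[became_free] = pos[became_free].mean(axis=1)


def motor_release(
    state: SystemState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    plus_end_flags: np.ndarray | None = None,
) -> None:
    """Detach motor heads: stochastic (p0*dt), plus-end arrival, over-stretch.

    Over-stretch (extension > r) forcibly releases one head — the more
    recently bound filament head, random on ties; an anchored head never
    releases.
    """
    pos = state.motor_head_positions()
    bound = state.mot_bound
    p_det = cfg.step_probability(cfg.motor_detach_rate)
    stoch = np.zeros_like(bound)
    stoch[bound] = rng.random(int(bound.sum())) < p_det
    release = stoch
    if plus_end_flags is not None:
        release = release | plus_end_flags
    _detach_motor_heads(state, release, pos)

    # over-stretch check on the survivors that still span two attachments
    att = state.motor_attached()
    active = att.all(axis=1)
    if not active.any():
        return
    pos = state.motor_head_positions()
    ext = np.linalg.norm(pos[:, 0, :] - pos[:, 1, :], axis=1)
    over = active & (ext > cfg.motor_reach)
    if not over.any():
        return
    idx = np.nonzero(over)[0]
    drop = np.zeros_like(bound)
    for m in idx:
        if state.mot_tethered[m]:
            h = 1  # the anchored head (A) never releases
        else:
            s0, s1 = state.mot_bind_step[m]
            if s0 == s1:
                h = int(rng.integers(0, 2))
            else:
                h = int(np.argmax(state.mot_bind_step[m]))
        drop[m, h] = True
    _detach_motor_heads(state, drop, pos)


# ---------------------------------------------------------------------------
# Turnover and boundary (stages 8, 9)
# ---------------------------------------------------------------------------


def _sever_filament_attachments(state: SystemState, fil_ids: np.ndarray) -> None:
    """Release every motor/crosslinker head bound to the given filaments."""
    if fil_ids.size == 0:
        return
    pos = state.motor_head_positions()
    hit = np.isin(state.mot_fil, fil_ids) & state.mot_bound
    _detach_motor_heads(state, hit, pos)
    release_crosslinkers_on(state, fil_ids)


def filament_turnover(
    state: SystemState,
    cfg: SimulationConfig,
    domain: HexagonDomain,
    rng: np.random.Generator,
    step: int,
) -> int:
    """Whole-filament replacement at rate ``p2`` per filament.

    Each mobile, non-exempt filament is independently replaced (uniform
    random position and orientation) with probability ``p2*dt``; all
    heads attached to it are severed.  Returns the replacement count.
    """
    eligible = state.fil_mobile & ~state.fil_turnover_exempt
    p = cfg.step_probability(cfg.filament_turnover_rate)
    draw = rng.random(state.n_filaments)
    replace = eligible & (draw < p)
    n_rep = int(replace.sum())
    if n_rep == 0:
        return 0
    ids = np.nonzero(replace)[0]
    _sever_filament_attachments(state, ids)
    state.fil_center[ids] = domain.sample_uniform(rng, n_rep)
    state.fil_angle[ids] = rng.uniform(0.0, 2.0 * np.pi, n_rep)
    state.fil_birth[ids] = step
    return n_rep


def enforce_boundary(
    state: SystemState,
    cfg: SimulationConfig,
    domain: HexagonDomain,
    rng: np.random.Generator,
) -> None:
    """Re-insert agents that left the hexagon.

    A mobile filament whose center exits is moved to a uniform random
    interior point (orientation preserved) and its bound heads are
    severed; fully free motors and crosslinkers outside are re-inserted
    uniformly.
    """
    out_fil = state.fil_mobile & ~domain.contains(state.fil_center)
    if out_fil.any():
        ids = np.nonzero(out_fil)[0]
        _sever_filament_attachments(state, ids)
        state.fil_center[ids] = domain.sample_uniform(rng, ids.size)
    att = state.motor_attached()
    free = ~att.any(axis=1) & ~state.mot_tethered
    out_mot = free & ~domain.contains(state.mot_pos)
    if out_mot.any():
        state.mot_pos[out_mot] = domain.sample_uniform(rng, int(out_mot.sum()))
    out_xl = ~state.xl_bound & ~domain.contains(state.xl_pos)
    if out_xl.any():
        state.xl_pos[out_xl] = domain.sample_uniform(rng, int(out_xl.sum()))


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------


@dataclass
class Snapshot:
    step: int
    time: float
    state: SystemState


@dataclass
class FrameSeries:
    """Trajectory of one run: per-step scalar series plus state snapshots."""

    config: SimulationConfig
    series: "object"            # pandas.DataFrame, one row per step
    snapshots: list[Snapshot] = field(default_factory=list)
    final_state: SystemState | None = None

    def snapshot_states(self) -> list[SystemState]:
        return [s.state for s in self.snapshots]


class Engine:
    """Stateful stepper; use :func:`simulate` for the common run-to-end case."""

    def __init__(
        self,
        config: SimulationConfig,
        initial_state: SystemState | None = None,
        rng: np.random.Generator | None = None,
    ):
        config.validate()
        self.cfg = config.replace()  # working copy: switches mutate it
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.domain = HexagonDomain(config.hexagon_circumradius)
        if initial_state is None:
            from .patterning import init_random

            initial_state = init_random(self.cfg, self.rng)
        self.state = initial_state
        self.drags = drag_coefficients(
            self.cfg.filament_length, self.cfg.filament_diameter, self.cfg.dynamic_viscosity
        )
        self.step_index = 0
        self._records: list[dict] = []
        self._snapshots: list[Snapshot] = []

    # -- switching ------------------------------------------------------

    def _apply_due_switches(self) -> None:
        for ev in self.cfg.switch_schedule:
            if ev.step == self.step_index:
                self.apply_switch(ev.field, ev.value)

    def apply_switch(self, fieldname: str, value: float) -> None:
        """Change one switchable parameter mid-run.

        Filament-length changes rescale rods about their centers: heads
        whose walk coordinate falls beyond the new half-length are
        released (they would sit past the new tip).  Drag coefficients
        are recomputed whenever geometry or viscosity changes.
        """
        old_len = self.cfg.filament_length
        setattr(self.cfg, fieldname, value)
        self.cfg.validate()
        if fieldname == "filament_length" and value < old_len:
            half = 0.5 * value
            pos = self.state.motor_head_positions()
            beyond = self.state.mot_bound & (np.abs(self.state.mot_len) > half)
            _detach_motor_heads(self.state, beyond, pos)
            xl_beyond = self.state.xl_bound & (
                np.abs(self.state.xl_len) > half
            ).any(axis=1)
            if xl_beyond.any():
                from .crosslinkers import release_crosslinker_mask

                release_crosslinker_mask(self.state, xl_beyond)
        if fieldname in ("filament_length", "dynamic_viscosity"):
            self.drags = drag_coefficients(
                self.cfg.filament_length,
                self.cfg.filament_diameter,
                self.cfg.dynamic_viscosity,
            )

    # -- stepping -------------------------------------------------------

    def step(self) -> dict:
        cfg, state, rng = self.cfg, self.state, self.rng
        self.step_index += 1
        step = self.step_index

        diffuse_free_motors(state, cfg, rng)
        motor_search_and_bind(state, cfg, rng, step)
        if state.n_crosslinkers:
            crosslinker_search_and_bind(state, cfg, rng)
        plus_end = motor_walk(state, cfg)
        acc = accumulate_forces(state, cfg)
        dissipation = step_filaments(state, acc, self.drags, cfg.timestep)
        motor_release(state, cfg, rng, plus_end)
        if state.n_crosslinkers:
            crosslinker_release(state, cfg, rng)
        filament_turnover(state, cfg, self.domain, rng, step)
        enforce_boundary(state, cfg, self.domain, rng)
        self._apply_due_switches()

        n_two, n_one, n_free = state.motor_state_counts()
        exerting = acc.motor_force_mag > 0
        record = {
            "step": step,
            "time": step * cfg.timestep,
            "mean_motor_force_pN": float(acc.motor_force_mag.mean())
            if state.n_motors
            else 0.0,
            "mean_exerting_force_pN": float(acc.motor_force_mag[exerting].mean())
            if exerting.any()
            else 0.0,
            "max_motor_force_pN": float(acc.motor_force_mag.max())
            if state.n_motors
            else 0.0,
            "n_two_bound": n_two,
            "n_one_bound": n_one,
            "n_free": n_free,
            "n_xl_bound": int(state.xl_bound.sum()),
            "elastic_energy": acc.elastic_energy,
            "dissipation": dissipation,
        }
        self._records.append(record)
        if step % self.cfg.snapshot_stride == 0:
            self._snapshots.append(Snapshot(step, step * cfg.timestep, state.copy()))
        return record

    def run(self, n_steps: int | None = None, callback=None) -> FrameSeries:
        import pandas as pd

        total = self.cfg.n_steps if n_steps is None else n_steps
        self._snapshots.append(Snapshot(0, 0.0, self.state.copy()))
        for _ in range(total):
            record = self.step()
            if callback is not None:
                callback(record)
        if not self._snapshots or self._snapshots[-1].step != self.step_index:
            self._snapshots.append(
                Snapshot(self.step_index, self.step_index * self.cfg.timestep, self.state.copy())
            )
        series = pd.DataFrame(self._records)
        return FrameSeries(
            config=self.cfg.replace(),
            series=series,
            snapshots=self._snapshots,
            final_state=self.state,
        )


def simulate(
    config: SimulationConfig, initial_state: SystemState | None = None
) -> FrameSeries:
    """Run a full simulation from a config (and optional prepared state)."""
    return Engine(config, initial_state=initial_state).run()
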