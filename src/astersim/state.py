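"""System state: filaments, motors and crosslinkers.

The engine operates on struct-of-arrays containers (:class:`SystemState`)
for speed; lightweight per-agent views (:class:`Filament`,
:class:`Motor`, :class:`Crosslinker`) are provided for inspection and
tests.

Conventions
-----------
* A filament is a rigid polar rod stored as center (x_i, y_i), angle
  theta_i and a mobility flag.  Its plus-end is
  ``center + (L/2)(cos theta, sin theta)``, the minus-end the opposite;
  ends are always derived, never stored.
* A motor has two heads.  A bound head carries the filament index and a
  signed walk coordinate ``len`` in [-L/2, +L/2] measured from the
  filament center toward the plus-end; its lab position is
  ``(x_i + len cos theta_i, y_i + len sin theta_i)``.
* A tethered motor has head A permanently anchored at a fixed point; it
  counts as "attached" for spring forces but never walks or releases.
* Crosslinkers reuse the head layout but never walk and bind/release
  both heads atomically.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "HeadState",
    "SystemState",
    "Filament",
    "MotorHead",
    "Motor",
    "Crosslinker",
    "attachment_point",
]

NO_FILAMENT = -1


class HeadState(IntEnum):
    FREE = 0
    BOUND = 1


def attachment_point(
    center: np.ndarray, angle: float | np.ndarray, walk_coord: float | np.ndarray
) -> np.ndarray:
    """Lab-frame position of a head bound at signed coordinate ``walk_coord``.

    ``a_j = x_i + len_j cos(theta_i)``, ``b_j = y_i + len_j sin(theta_i)``.
    """
    center = np.asarray(center, dtype=float)
    u = np.stack(
        [np.cos(np.asarray(angle, dtype=float)), np.sin(np.asarray(angle, dtype=float))],
        axis=-1,
    )
    return center + np.asarray(walk_coord, dtype=float)[..., None] * u


@dataclass
class SystemState:
    """Struct-of-arrays snapshot of every agent.

    Attributes with prefix ``fil_`` have leading dimension N (filaments),
    ``mot_`` dimension M (motors, trailing dimension 2 = heads A/B),
    ``xl_`` dimension C (crosslinkers).
    """

    # filaments
    fil_center: np.ndarray      # (N, 2) float
    fil_angle: np.ndarray       # (N,) float
    fil_mobile: np.ndarray      # (N,) bool
    fil_turnover_exempt: np.ndarray  # (N,) bool
    fil_birth: np.ndarray       # (N,) int
    # motors
    mot_bound: np.ndarray       # (M, 2) bool
    mot_fil: np.ndarray         # (M, 2) int, NO_FILAMENT when free
    mot_len: np.ndarray         # (M, 2) float walk coordinate
    mot_pos: np.ndarray         # (M, 2) float: position of a fully free motor
    mot_bind_step: np.ndarray   # (M, 2) int step at which the head last bound
    mot_tethered: np.ndarray    # (M,) bool; head A anchored
    mot_anchor: np.ndarray      # (M, 2) float, NaN when untethered
    # crosslinkers
    xl_bound: np.ndarray        # (C,) bool; both heads bind/release together
    xl_fil: np.ndarray          # (C, 2) int
    xl_len: np.ndarray          # (C, 2) float, frozen at binding
    xl_pos: np.ndarray          # (C, 2) float, free crosslinker position

    @classmethod
    def empty(cls, n_filaments: int, n_motors: int, n_crosslinkers: int) -> "SystemState":
        n, m, c = n_filaments, n_motors, n_crosslinkers
        return cls(
            fil_center=np.zeros((n, 2)),
            fil_angle=np.zeros(n),
            fil_mobile=np.ones(n, dtype=bool),
            fil_turnover_exempt=np.zeros(n, dtype=bool),
            fil_birth=np.zeros(n, dtype=np.int64),
            mot_bound=np.zeros((m, 2), dtype=bool),
            mot_fil=np.full((m, 2), NO_FILAMENT, dtype=np.int64),
            mot_len=np.zeros((m, 2)),
            mot_pos=np.zeros((m, 2)),
            mot_bind_step=np.full((m, 2), -1, dtype=np.int64),
            mot_tethered=np.zeros(m, dtype=bool),
            mot_anchor=np.full((m, 2), np.nan),
            xl_bound=np.zeros(c, dtype=bool),
            xl_fil=np.full((c, 2), NO_FILAMENT, dtype=np.int64),
            xl_len=np.zeros((c, 2)),
            xl_pos=np.zeros((c, 2)),
        )

    # -- sizes ----------------------------------------------------------

    @property
    def n_filaments(self) -> int:
        return self.fil_center.shape[0]

    @property
    def n_motors(self) -> int:
        return self.mot_bound.shape[0]

    @property
    def n_crosslinkers(self) -> int:
        return self.xl_bound.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(
            **{k: v.copy() for k, v in self.__dict__.items() if isinstance(v, np.ndarray)}
        )

    # -- derived geometry ----------------------------------------------

    def fil_direction(self) -> np.ndarray:
        """(N, 2) unit vectors from minus- to plus-end."""
        return np.column_stack([np.cos(self.fil_angle), np.sin(self.fil_angle)])

    def plus_ends(self, filament_length: float) -> np.ndarray:
        return self.fil_center + 0.5 * filament_length * self.fil_direction()

    def minus_ends(self, filament_length: float) -> np.ndarray:
        return self.fil_center - 0.5 * filament_length * self.fil_direction()

    def motor_attached(self) -> np.ndarray:
        """(M, 2) bool: head holds an attachment (filament-bound or anchored)."""
        att = self.mot_bound.copy()
        att[self.mot_tethered, 0] = True
        return att

    def motor_head_positions(self) -> np.ndarray:
        """(M, 2, 2) lab positions of both heads of every motor.

        Bound heads ride their filament; the anchored head of a tethered
        motor sits at its anchor; a free head of a partially attached
        motor coincides with its partner (zero rest length); both heads
        of a fully free motor coincide at ``mot_pos``.
        """
        m = self.n_motors
        pos = np.empty((m, 2, 2))
        pos[:, 0, :] = self.mot_pos
        pos[:, 1, :] = self.mot_pos
        if self.mot_bound.any():
            mm, hh = np.nonzero(self.mot_bound)
            f = self.mot_fil[mm, hh]
            ang = self.fil_angle[f]
            ln = self.mot_len[mm, hh]
            pos[mm, hh, 0] = self.fil_center[f, 0] + ln * np.cos(ang)
            pos[mm, hh, 1] = self.fil_center[f, 1] + ln * np.sin(ang)
        anchored = self.mot_tethered
        if anchored.any():
            pos[anchored, 0, :] = self.mot_anchor[anchored]
        att = self.motor_attached()
        # a lone free head rides its attached partner
        for h, other in ((0, 1), (1, 0)):
            ride = ~att[:, h] & att[:, other]
            if ride.any():
                pos[ride, h, :] = pos[ride, other, :]
        return pos

    def motor_extension(self) -> np.ndarray:
        """(M,) distance between the two head positions."""
        pos = self.motor_head_positions()
        return np.linalg.norm(pos[:, 0, :] - pos[:, 1, :], axis=1)

    def motor_state_counts(self) -> tuple[int, int, int]:
        """(two_attached, one_attached, free) motor counts."""
        n_att = self.motor_attached().sum(axis=1)
        return int((n_att == 2).sum()), int((n_att == 1).sum()), int((n_att == 0).sum())

    def xl_head_positions(self) -> np.ndarray:
        """(C, 2, 2) crosslinker head positions (both at xl_pos when free)."""
        pos = np.repeat(self.xl_pos[:, None, :], 2, axis=1).astype(float)
        b = self.xl_bound
        for h in (0, 1):
            f = self.xl_fil[b, h]
            pos[b, h, :] = attachment_point(
                self.fil_center[f], self.fil_angle[f], self.xl_len[b, h]
            )
        return pos


# ---------------------------------------------------------------------------
# Per-agent views (convenience layer over SystemState)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Filament:
    id: int
    center: np.ndarray
    angle: float
    mobile: bool
    birth_step: int

    def plus_end(self, filament_length: float) -> np.ndarray:
        return attachment_point(self.center, self.angle, 0.5 * filament_length)

    def minus_end(self, filament_length: float) -> np.ndarray:
        return attachment_point(self.center, self.angle, -0.5 * filament_length)


@dataclass(frozen=True)
class MotorHead:
    state: HeadState
    bound_filament_id: int | None
    walk_coord: float
    position: np.ndarray


@dataclass(frozen=True)
class Motor:
    id: int
    head_a: MotorHead
    head_b: MotorHead
    tethered: bool
    anchor: np.ndarray | None

    @property
    def state(self) -> str:
        n = (self.head_a.state == HeadState.BOUND) + (self.head_b.state == HeadState.BOUND)
        if self.tethered:
            n += 1
        return {0: "free", 1: "one-bound", 2: "two-bound"}[int(n)]


@dataclass(frozen=True)
class Crosslinker:
    id: int
    head_a: MotorHead
    head_b: MotorHead


def get_filament(state: SystemState, i: int) -> Filament:
    return Filament(
        id=i,
        center=state.fil_center[i].copy(),
        angle=float(state.fil_angle[i]),
        mobile=bool(state.fil_mobile[i]),
        birth_step=int(state.fil_birth[i]),
    )


def _head_view(state: SystemState, pos: np.ndarray, kind: str, j: int, h: int) -> MotorHead:
    if kind == "motor":
        bound = bool(state.mot_bound[j, h])
        fil = int(state.mot_fil[j, h])
        ln = float(state.mot_len[j, h])
    else:
        bound = bool(state.xl_bound[j])
        fil = int(state.xl_fil[j, h])
        ln = float(state.xl_len[j, h])
    return MotorHead(
        state=HeadState.BOUND if bound else HeadState.FREE,
        bound_filament_id=fil if bound else None,
        walk_coord=ln,
        position=pos.copy(),
    )


def get_motor(state: SystemState, j: int) -> Motor:
    pos = state.motor_head_positions()[j]
    tethered = bool(state.mot_tethered[j])
    return Motor(
        id=j,
        head_a=_head_view(state, pos[0], "motor", j, 0),
        head_b=_head_view(state, pos[1], "motor", j, 1),
        tethered=tethered,
        anchor=state.mot_anchor[j].copy() if tethered else None,
    )


def get_crosslinker(state: SystemState, j: int) -> Crosslinker:
    pos = state.xl_head_positions()[j]
    return Crosslinker(
        id=j,
        head_a=_head_view(state, pos[0], "xl", j, 0),
        head_b=_head_view(state, pos[1], "xl", j, 1),
    )
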