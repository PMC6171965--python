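"""Simulation configuration.

All quantities use a single global unit system: micrometers, seconds and
piconewtons (energies therefore in pN um).  The default parameter set is
the "standard" physiological set used throughout: 1000 rigid 1-um actin
filaments and 5000 two-headed myosin mini-filament motors in a hexagonal
cortex patch, motor stiffness 3 pN/um, plus-end directed walking at
1 um/s, attachment 10/s, detachment 1/s, whole-filament turnover 0.7/s,
search/stretch radius 0.3 um, viscosity 1 pN s/um^2, 1000 steps of 10 ms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import yaml

__all__ = ["SimulationConfig", "SwitchEvent", "SWITCHABLE_FIELDS"]

#: Short parameter symbols accepted by switch schedules and CLI overrides,
#: mapped to config field names.
SYMBOL_TO_FIELD = {
    "N": "n_filaments",
    "M": "n_motors",
    "L": "filament_length",
    "di": "filament_diameter",
    "k": "motor_stiffness",
    "v": "motor_velocity",
    "p1": "motor_attach_rate",
    "p0": "motor_detach_rate",
    "p2": "filament_turnover_rate",
    "r": "motor_reach",
    "eta": "dynamic_viscosity",
    "dt": "timestep",
}

#: Fields that may be changed mid-run by a switch schedule.
SWITCHABLE_FIELDS = frozenset(
    {
        "motor_stiffness",
        "motor_reach",
        "filament_length",
        "motor_velocity",
        "motor_detach_rate",
        "motor_attach_rate",
        "filament_turnover_rate",
        "dynamic_viscosity",
    }
)


@dataclass(frozen=True)
class SwitchEvent:
    """A mid-run parameter change, applied after ``step`` completes."""

    step: int
    field: str
    value: float

    def __post_init__(self) -> None:
        name = SYMBOL_TO_FIELD.get(self.field, self.field)
        object.__setattr__(self, "field", name)
        if name not in SWITCHABLE_FIELDS:
            raise ValueError(
                f"'{name}' is not switchable; allowed: {sorted(SWITCHABLE_FIELDS)}"
            )
        if self.step < 0:
            raise ValueError("switch step must be >= 0")


@dataclass
class SimulationConfig:
    """Complete parameter set for one simulation run."""

    n_filaments: int = 1000
    n_motors: int = 5000
    n_crosslinkers: int = 0
    filament_length: float = 1.0        # L, um
    filament_diameter: float = 0.008    # di, um
    motor_stiffness: float = 3.0        # k, pN/um
    motor_velocity: float = 1.0         # v, um/s (plus-end directed)
    motor_attach_rate: float = 10.0     # p1, 1/s
    motor_detach_rate: float = 1.0      # p0, 1/s
    filament_turnover_rate: float = 0.7  # p2, 1/s per filament
    motor_reach: float = 0.3            # r, um; search radius AND max stretch
    dynamic_viscosity: float = 1.0      # eta, pN s/um^2
    timestep: float = 0.01              # dt, s
    n_steps: int = 1000
    hexagon_circumradius: float = 2.5   # um (calibrated once; see docs/methods.md)
    free_motor_diffusion_step: float = 0.05  # um per step, isotropic
    crosslinker_reach: float = 0.04     # um; max stretch / pair separation
    crosslinker_angle_tol: float = 0.39269908169872414  # pi/8 rad
    crosslinker_stiffness: float | None = 6.0  # pN/um; None -> motor_stiffness
    crosslinker_attach_rate: float | None = None  # 1/s; None -> motor_attach_rate
    crosslinker_unbind_rate: float = 0.0  # 1/s; bound crosslinkers are fixed by default
    crosslinker_break_on_overstretch: bool = False  # release when extension > reach
    binding_choice: str = "random"  # candidate filament choice: "random" or "nearest"
    free_attach_deterministic: bool = False  # free motors may grab any filament in reach
    seed: int = 0
    snapshot_stride: int = 100
    switch_schedule: list[SwitchEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.switch_schedule = [
            ev if isinstance(ev, SwitchEvent) else SwitchEvent(*ev)
            for ev in self.switch_schedule
        ]
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        c = self
        if c.n_filaments < 0 or c.n_motors < 0 or c.n_crosslinkers < 0:
            raise ValueError("agent counts must be >= 0")
        if c.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if not (c.filament_length > c.filament_diameter > 0):
            raise ValueError("require filament_length > filament_diameter > 0")
        for name in (
            "motor_stiffness",
            "motor_velocity",
            "motor_attach_rate",
            "motor_detach_rate",
            "filament_turnover_rate",
            "motor_reach",
            "crosslinker_reach",
            "crosslinker_angle_tol",
            "crosslinker_unbind_rate",
            "free_motor_diffusion_step",
        ):
            if getattr(c, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if c.dynamic_viscosity <= 0:
            raise ValueError("dynamic_viscosity must be > 0")
        if c.hexagon_circumradius <= 0:
            raise ValueError("hexagon_circumradius must be > 0")
        if c.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if c.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be >= 1")
        if c.binding_choice not in ("nearest", "random"):
            raise ValueError("binding_choice must be 'nearest' or 'random'")

    # -- derived quantities --------------------------------------------

    @property
    def xl_stiffness(self) -> float:
        return (
            self.motor_stiffness
            if self.crosslinker_stiffness is None
            else self.crosslinker_stiffness
        )

    @property
    def xl_attach_rate(self) -> float:
        return (
            self.motor_attach_rate
            if self.crosslinker_attach_rate is None
            else self.crosslinker_attach_rate
        )

    def step_probability(self, rate: float) -> float:
        """Convert a rate (1/s) into a per-step probability rate*dt, clipped to 1.

        For all standard rates rate*dt <= 0.1, so the difference from
        1 - exp(-rate*dt) is below 0.5%.
        """
        return min(rate * self.timestep, 1.0)

    # -- (de)serialization ---------------------------------------------

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["switch_schedule"] = [
            [ev.step, ev.field, ev.value] for ev in self.switch_schedule
        ]
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def with_overrides(self, overrides: Iterable[tuple[str, Any]]) -> "SimulationConfig":
        """Apply ``(key, value)`` overrides; keys may be field names or symbols."""
        changes: dict[str, Any] = {}
        fields = {f.name: f for f in dataclasses.fields(self)}
        for key, value in overrides:
            name = SYMBOL_TO_FIELD.get(key, key)
            if name not in fields:
                raise ValueError(
                    f"unknown config key '{key}'; valid keys: {sorted(fields)}"
                )
            changes[name] = value
        return self.replace(**changes)
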