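"""Scenario configuration files, run manifests, and CSV serialization.

The canonical configuration dialect is YAML. A minimal file is::

    protein_g_per_day: 71
    condition: normal

Optional sections override physiology (``body_mass_kg``), individual kinetic
constants (``kinetics:``), the zonation timing (``schedule:``) and solver
settings (``solver:``). Unknown keys anywhere are rejected by name: a silently
ignored typo in a parameter override would corrupt a study.

Every simulation output can be accompanied by a :class:`RunManifest` -- the
fully resolved parameter set, schedule, solver options, tool version and a
digest of the input config -- sufficient to reproduce the run bit-for-bit
(the pipeline is deterministic; there is no randomness anywhere).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .params import (
    KineticParams,
    LiverCondition,
    PhysiologyConstants,
    Scenario,
    blood_volume_for_mass,
    build_scenario,
)
from .simulate import DEFAULT_DURATION_S, SolverOptions, Trajectory, ZonationSchedule

__all__ = ["RunConfig", "RunManifest", "load_config", "write_scenario_csv",
           "write_trajectory_csv"]

_KINETIC_FIELDS = {f.name for f in dataclasses.fields(KineticParams)}
_SOLVER_KEYS = {"method", "rtol", "atol", "points_per_phase"}
_SCHEDULE_KEYS = {"phase1_s", "phase2_s", "cycle_s"}
_TOP_KEYS = {
    "protein_g_per_day",
    "condition",
    "body_mass_kg",
    "initial_state",
    "kinetics",
    "schedule",
    "solver",
    "duration_s",
}


@dataclass(frozen=True)
class RunConfig:
    """A resolved configuration: scenario plus run options."""

    scenario: Scenario
    schedule: ZonationSchedule
    solver: SolverOptions
    duration_s: float
    config_sha256: str


@dataclass(frozen=True)
class RunManifest:
    """Provenance record accompanying every simulation output."""

    version: str
    created_utc: str
    config_sha256: str
    protein_g_per_day: float
    condition: str
    physiology: dict
    kinetics: dict
    initial_state: list
    schedule: dict
    solver: dict
    duration_s: float

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "RunManifest":
        s = cfg.scenario
        return cls(
            version=__version__,
            created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            config_sha256=cfg.config_sha256,
            protein_g_per_day=s.diet.protein_g_per_day,
            condition=s.condition.value,
            physiology=dataclasses.asdict(s.physiology),
            kinetics=dataclasses.asdict(s.kinetics),
            initial_state=list(s.initial_state),
            schedule=dataclasses.asdict(cfg.schedule),
            solver=dataclasses.asdict(cfg.solver),
            duration_s=cfg.duration_s,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    def rebuild(self) -> RunConfig:
        """Reconstruct the runnable configuration from the manifest alone."""
        scenario = Scenario(
            diet=build_scenario(self.protein_g_per_day, self.condition).diet,
            condition=LiverCondition.parse(self.condition),
            physiology=PhysiologyConstants(**self.physiology),
            kinetics=KineticParams(**self.kinetics),
            initial_state=tuple(self.initial_state),
        )
        return RunConfig(
            scenario=scenario,
            schedule=ZonationSchedule(**self.schedule),
            solver=SolverOptions(**self.solver),
            duration_s=self.duration_s,
            config_sha256=self.config_sha256,
        )


def _reject_unknown(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown {context} key(s): {', '.join(sorted(map(str, unknown)))}; "
            f"valid keys: {', '.join(sorted(allowed))}"
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML scenario configuration.

    Raises :class:`ConfigError` naming the offending key on any schema
    violation; an unknown ``condition`` value lists the valid choices.
    """
    raw_text = Path(path).read_text()
    digest = hashlib.sha256(raw_text.encode()).hexdigest()
    data = yaml.safe_load(raw_text)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping at the top level")
    _reject_unknown(data, _TOP_KEYS, "config")
    if "protein_g_per_day" not in data:
        raise ConfigError("missing required key: protein_g_per_day")

    condition = data.get("condition", "normal")
    try:
        condition = LiverCondition.parse(condition)
    except Exception as exc:
        raise ConfigError(str(exc)) from None

    physiology = None
    if "body_mass_kg" in data:
        mass = float(data["body_mass_kg"])
        physiology = PhysiologyConstants(
            body_mass_kg=mass, blood_volume_l=blood_volume_for_mass(mass)
        )

    initial_state = tuple(data.get("initial_state", (0.0, 5.5, 0.0)))
    if len(initial_state) != 3:
        raise ConfigError("initial_state must have 3 entries (nh3, urea, gln in mM)")

    scenario = build_scenario(
        float(data["protein_g_per_day"]),
        condition,
        physiology=physiology,
        initial_state=initial_state,
    )

    overrides = data.get("kinetics", {}) or {}
    if not isinstance(overrides, dict):
        raise ConfigError("kinetics must be a mapping of parameter overrides")
    _reject_unknown(overrides, _KINETIC_FIELDS, "kinetics")
    if overrides:
        scenario = scenario.with_kinetics(
            **{k: float(v) for k, v in overrides.items()}
        )

    sched_data = data.get("schedule", {}) or {}
    _reject_unknown(sched_data, _SCHEDULE_KEYS, "schedule")
    schedule = ZonationSchedule(**{k: float(v) for k, v in sched_data.items()})

    solver_data = data.get("solver", {}) or {}
    _reject_unknown(solver_data, _SOLVER_KEYS, "solver")
    solver = SolverOptions(**solver_data)

    return RunConfig(
        scenario=scenario,
        schedule=schedule,
        solver=solver,
        duration_s=float(data.get("duration_s", DEFAULT_DURATION_S)),
        config_sha256=digest,
    )


def write_scenario_csv(scenario: Scenario, path: str | Path) -> pd.DataFrame:
    """Emit the resolved scenario as a flat parameter/value table (provenance)."""
    rows = [
        ("protein_g_per_day", scenario.diet.protein_g_per_day, "g/day"),
        ("nitrogen_mass_fraction", scenario.diet.nitrogen_mass_fraction, "1"),
        ("fecal_loss_fraction", scenario.diet.fecal_loss_fraction, "1"),
        ("condition", scenario.condition.value, ""),
        ("body_mass_kg", scenario.physiology.body_mass_kg, "kg"),
        ("liver_mass_g", scenario.physiology.liver_mass_g, "g"),
        ("blood_volume_l", scenario.physiology.blood_volume_l, "L"),
        ("sinusoid_transit_s", scenario.physiology.sinusoid_transit_s, "s"),
    ]
    for f in dataclasses.fields(KineticParams):
        unit = "mmol/min" if f.name.startswith(("v", "V")) else "mM"
        rows.append((f.name, getattr(scenario.kinetics, f.name), unit))
    for name, value in zip(("initial_nh3", "initial_urea", "initial_gln"),
                           scenario.initial_state):
        rows.append((name, value, "mM"))
    df = pd.DataFrame(rows, columns=["parameter", "value", "unit"])
    df.to_csv(path, index=False)
    return df


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> pd.DataFrame:
    """Tidy long-format trajectory CSV.

    Columns: time_s, species, concentration_mM, phase, and a parallel
    concentration_uM column filled for ammonia rows (the unit blood ammonia
    is conventionally reported in).
    """
    df = traj.to_frame()
    df["concentration_uM"] = df["concentration_mM"].where(
        df["species"] == "nh3"
    ) * 1000.0
    df.to_csv(path, index=False)
    return df
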