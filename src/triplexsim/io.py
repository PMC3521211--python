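"""Readers, writers and fixtures.

File formats are deliberately plain: parameter tables are CSV with
columns ``name,value,description``; run configuration is YAML;
trajectories and PRCC results are CSV.  Everything round-trips so a run
can be reproduced from its echoed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    PARAM_DESCRIPTIONS,
    PARAM_NAMES,
    STATE_LABELS,
    STEPS_PER_DAY,
    STEPS_PER_WEEK,
    ParameterSet,
    default_parameters,
)
from .protocols import Protocol, build_protocol
from .simulate import DEATH_THRESHOLD, DEFAULT_SUBSTEPS, Trajectory
from .sensitivity import PRCCResult

__all__ = [
    "RunConfig",
    "load_parameters",
    "write_parameters",
    "load_config",
    "protocol_from_config",
    "write_trajectory",
    "read_trajectory",
    "write_prcc",
    "make_fixtures",
]

TRAJECTORY_COLUMNS = ["step", "day", "week", *STATE_LABELS]


def load_parameters(path: str | Path) -> ParameterSet:
    """Read and validate a complete parameter table from CSV."""
    table = pd.read_csv(path, float_precision="round_trip")
    required = {"name", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"parameter table must have columns {sorted(required)}")
    names = table["name"].tolist()
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate parameter names: {', '.join(dupes)}")
    values = {}
    for name, value in zip(table["name"], table["value"]):
        try:
            values[str(name)] = float(value)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric value for parameter {name!r}: {value!r}")
    return ParameterSet.from_dict(values)


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter table as CSV (full float precision)."""
    rows = [
        {
            "name": name,
            "value": repr(float(getattr(params, name))),
            "description": PARAM_DESCRIPTIONS.get(name, ""),
        }
        for name in PARAM_NAMES
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated contents of a YAML run configuration."""

    parameters: ParameterSet
    protocol: Protocol
    end_week: int = 57
    threshold: float = DEATH_THRESHOLD
    n_substeps: int = DEFAULT_SUBSTEPS
    stop_at_death: bool = True
    sensitivity: dict | None = None


_PROTOCOL_KEYS = {"kind", "start_week", "end_week", "dose_q", "custom_days"}
_SIM_KEYS = {"end_week", "threshold", "substeps", "stop_at_death"}
_SENS_KEYS = {"n_samples", "seed", "alpha", "ranges", "fixed", "output", "rel_width"}
_TOP_KEYS = {"parameters", "parameter_overrides", "protocol", "simulation", "sensitivity"}


def protocol_from_config(block: dict) -> Protocol:
    unknown = set(block) - _PROTOCOL_KEYS
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    return build_protocol(
        kind=block.get("kind", "untreated"),
        start_week=int(block.get("start_week", 6)),
        end_week=int(block.get("end_week", 57)),
        dose_q=float(block.get("dose_q", 50.0)),
        custom_days=block.get("custom_days"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    if "parameters" in raw:
        params = load_parameters(Path(path).parent / raw["parameters"])
    else:
        params = default_parameters()
    overrides = raw.get("parameter_overrides") or {}
    unknown = set(overrides) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
    if overrides:
        params = params.replace(**{k: float(v) for k, v in overrides.items()})
        params.validate()

    sim = raw.get("simulation") or {}
    unknown = set(sim) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    sens = raw.get("sensitivity")
    if sens is not None:
        unknown = set(sens) - _SENS_KEYS
        if unknown:
            raise ValueError(f"unknown sensitivity keys: {sorted(unknown)}")

    proto_block = raw.get("protocol") or {"kind": "untreated"}
    end_week = int(sim.get("end_week", proto_block.get("end_week", 57)))
    proto_block = {**proto_block, "end_week": end_week}
    return RunConfig(
        parameters=params,
        protocol=protocol_from_config(proto_block),
        end_week=end_week,
        threshold=float(sim.get("threshold", DEATH_THRESHOLD)),
        n_substeps=int(sim.get("substeps", DEFAULT_SUBSTEPS)),
        stop_at_death=bool(sim.get("stop_at_death", True)),
        sensitivity=sens,
    )


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    steps = np.asarray(traj.steps)
    frame = pd.DataFrame(
        {
            "step": steps,
            "day": steps / STEPS_PER_DAY,
            "week": steps / STEPS_PER_WEEK,
        }
    )
    for label, column in zip(STATE_LABELS, traj.states.T):
        frame[label] = column
    return frame


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    trajectory_frame(traj).to_csv(path, index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns: {missing}")
    return frame


def write_prcc(result: PRCCResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False)


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Emit the default parameter table, preset protocol configs and a
    decoupled exponential-decay scenario used by closed-form tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    params_path = out / "default_parameters.csv"
    write_parameters(default_parameters(), params_path)
    written.append(params_path)

    for kind in ("untreated", "early", "chronic"):
        path = out / f"protocol_{kind}.yaml"
        with open(path, "w") as handle:
            yaml.safe_dump(
                {
                    "protocol": {
                        "kind": kind,
                        "start_week": 6,
                        "end_week": 57,
                        "dose_q": 50.0,
                    }
                },
                handle,
                sort_keys=False,
            )
        written.append(path)

    # pure-decay scenario: couplings and influx off, one population seeded
    # by a single injection, half-life 9 steps
    decay = ParameterSet(mu_1=np.log(2) / 9, q=100.0)
    decay_params = out / "decay_parameters.csv"
    write_parameters(decay, decay_params)
    written.append(decay_params)
    decay_config = out / "decay_scenario.yaml"
    with open(decay_config, "w") as handle:
        yaml.safe_dump(
            {
                "parameters": decay_params.name,
                "protocol": {
                    "kind": "custom",
                    "start_week": 0,
                    "end_week": 4,
                    "dose_q": 100.0,
                    "custom_days": [0],
                },
                "simulation": {"end_week": 4},
            },
            handle,
            sort_keys=False,
        )
    written.append(decay_config)
    return written
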