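"""Time integration of the tumor-immune system with impulsive dosing.

The model is reported on an 8-hour grid starting at birth (step 0) from
the all-zero state: every population, including cancer cells, only
appears afterwards (cancer cells through the transgenic influx ``p``,
immune populations through vaccination).  At each grid step any scheduled
injection is applied as an impulse (VC += q) and the system is then
advanced one step with classical 4th-order Runge-Kutta on a fixed
sub-step grid.

A simulated mouse is considered dead at the first grid step where the
cancer-cell count reaches the carcinoma in situ threshold of 1e5 cells —
the model's point of no return.  Trajectories may optionally continue
past that step, but are then extrapolations beyond the model's domain of
validity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    STATE_FIELDS,
    STEPS_PER_WEEK,
    ModelState,
    ParameterSet,
    max_linear_loss_rate,
    rhs_array,
)
from .protocols import Protocol

__all__ = [
    "DEATH_THRESHOLD",
    "DEFAULT_SUBSTEPS",
    "Trajectory",
    "SurvivalSummary",
    "step_integrate",
    "simulate",
    "simulate_batch",
    "survival_table",
]

logger = logging.getLogger(__name__)

# carcinoma in situ point of no return: 1e5 cancer cells per ul
DEATH_THRESHOLD: float = 1e5
# Baseline RK4 sub-steps per 8-hour step.  The high-antibody phases of a
# treated run are locally stiff (linear loss rates of tens per step), so
# each step additionally raises the sub-step count until lambda*h stays
# well inside the RK4 stability interval (see _stable_substeps).
DEFAULT_SUBSTEPS: int = 8
# keep lambda*h <= 2, comfortably below the RK4 real-axis stability
# bound of about 2.79
_STABILITY_MARGIN: float = 2.0


def _stable_substeps(y: np.ndarray, params: ParameterSet, base: int) -> int:
    lam = max_linear_loss_rate(y, params)
    return max(base, int(np.ceil(lam / _STABILITY_MARGIN)))


@dataclass
class Trajectory:
    """An integrated time course on the 8-hour grid.

    ``states`` has one row per grid point (row 0 is the initial
    condition), columns in STATE_FIELDS order.  ``injections_applied``
    records the (step, dose) impulses actually delivered within the
    horizon.  ``death_step`` is the first grid step whose cancer-cell
    count reached the threshold, or None if censored at the horizon.
    ``clamp_count`` counts negative components clamped to zero during
    integration (a numerical diagnostic; 0 in normal runs).
    """

    steps: np.ndarray
    states: np.ndarray
    injections_applied: list[tuple[int, float]]
    death_step: int | None
    threshold: float
    clamp_count: int = 0

    def column(self, name: str) -> np.ndarray:
        """Time course of one population, by lower-case field name."""
        return self.states[:, STATE_FIELDS.index(name.lower())]

    @property
    def death_week(self) -> float | None:
        """Age at death in weeks (step / 21), or None if censored."""
        if self.death_step is None:
            return None
        return self.death_step / STEPS_PER_WEEK


@dataclass(frozen=True)
class SurvivalSummary:
    """Outcome of one protocol run: death step/week or censoring."""

    protocol: str
    death_step: int | None
    death_week: float | None
    censored: bool


def _rk4_step(y: np.ndarray, params: ParameterSet, n_substeps: int) -> np.ndarray:
    h = 1.0 / n_substeps
    for _ in range(n_substeps):
        k1 = rhs_array(y, params)
        k2 = rhs_array(y + 0.5 * h * k1, params)
        k3 = rhs_array(y + 0.5 * h * k2, params)
        k4 = rhs_array(y + h * k3, params)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return y


def step_integrate(
    state: ModelState,
    params: ParameterSet,
    n_substeps: int = DEFAULT_SUBSTEPS,
) -> ModelState:
    """Advance one 8-hour step by RK4 with ``n_substeps`` sub-steps.

    Negative components (possible only through truncation error near
    zero) are clamped to 0 and logged.
    """
    if n_substeps < 1:
        raise ValueError("n_substeps must be >= 1")
    y = state.to_array()
    y = _rk4_step(y, params, _stable_substeps(y, params, n_substeps))
    if not np.all(np.isfinite(y)):
        bad = STATE_FIELDS[int(np.argwhere(~np.isfinite(y))[0][0])]
        raise FloatingPointError(f"integration produced non-finite {bad!r}")
    if np.any(y < 0):
        logger.warning("clamped %d negative component(s) to zero", int(np.sum(y < 0)))
        y = np.maximum(y, 0.0)
    return ModelState.from_array(y)


def simulate(
    params: ParameterSet,
    protocol: Protocol,
    end_week: int = 57,
    threshold: float = DEATH_THRESHOLD,
    stop_at_death: bool = True,
    n_substeps: int = DEFAULT_SUBSTEPS,
    initial_state: ModelState | None = None,
) -> Trajectory:
    """Integrate from birth to ``end_week`` under an injection calendar.

    At each grid step the scheduled dose (if any) is first added to VC,
    then the system advances one 8-hour step.  The first grid step with
    CC >= ``threshold`` is recorded as the death step; with
    ``stop_at_death`` the trajectory is truncated there, otherwise
    integration continues to the horizon (beyond model validity).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    params.validate()
    n_steps = end_week * STEPS_PER_WEEK
    dose_at = dict.fromkeys(protocol.injection_steps, protocol.dose_q)

    y = (initial_state or ModelState()).to_array()
    states = np.empty((n_steps + 1, len(STATE_FIELDS)))
    states[0] = y
    injections: list[tuple[int, float]] = []
    death_step: int | None = None
    clamp_count = 0

    cc_idx = STATE_FIELDS.index("cc")
    if y[cc_idx] >= threshold:
        death_step = 0

    last = n_steps
    for step in range(n_steps):
        if death_step is not None and stop_at_death:
            last = step
            break
        dose = dose_at.get(step, 0.0)
        if dose:
            y = y.copy()
            y[0] += dose
            injections.append((step, dose))
        y = _rk4_step(y, params, _stable_substeps(y, params, n_substeps))
        if not np.all(np.isfinite(y)):
            bad = STATE_FIELDS[int(np.argwhere(~np.isfinite(y))[0][0])]
            raise FloatingPointError(
                f"integration produced non-finite {bad!r} at step {step + 1}"
            )
        neg = y < 0
        if np.any(neg):
            clamp_count += int(np.sum(neg))
            y = np.maximum(y, 0.0)
        states[step + 1] = y
        if death_step is None and y[cc_idx] >= threshold:
            death_step = step + 1
    else:
        last = n_steps

    if clamp_count:
        logger.warning("clamped %d negative component(s) to zero", clamp_count)
    return Trajectory(
        steps=np.arange(last + 1),
        states=states[: last + 1],
        injections_applied=injections,
        death_step=death_step,
        threshold=threshold,
        clamp_count=clamp_count,
    )


def simulate_batch(
    params: ParameterSet,
    protocol: Protocol,
    end_week: int = 57,
    record_steps: np.ndarray | None = None,
    output: str = "cc",
    n_substeps: int = DEFAULT_SUBSTEPS,
) -> np.ndarray:
    """Vectorized integration of many parameter sets at once.

    ``params`` holds one array of length n per varied field (scalars are
    shared).  All rows are integrated over the full horizon without
    death truncation so the output matrix is rectangular, as required by
    the time-course sensitivity analysis.  Returns the ``output``
    population sampled at ``record_steps`` (default: every step), shape
    (n, len(record_steps)).
    """
    n = max(
        (np.size(getattr(params, name)) for name in params.to_dict()),
        default=1,
    )
    n_steps = end_week * STEPS_PER_WEEK
    if record_steps is None:
        record_steps = np.arange(n_steps + 1)
    record_steps = np.asarray(record_steps, dtype=int)
    if record_steps.size and (record_steps.min() < 0 or record_steps.max() > n_steps):
        raise ValueError("record_steps outside the simulation horizon")
    record_set = {int(s): i for i, s in enumerate(record_steps)}

    out_idx = STATE_FIELDS.index(output.lower())
    dose_at = dict.fromkeys(protocol.injection_steps, protocol.dose_q)
    y = np.zeros((n, len(STATE_FIELDS)))
    result = np.empty((n, record_steps.size))
    if 0 in record_set:
        result[:, record_set[0]] = y[:, out_idx]
    for step in range(n_steps):
        dose = dose_at.get(step, 0.0)
        if dose:
            y[:, 0] += dose
        y = _rk4_step(y, params, _stable_substeps(y, params, n_substeps))
        np.maximum(y, 0.0, out=y)
        if step + 1 in record_set:
            result[:, record_set[step + 1]] = y[:, out_idx]
    return result


def survival_table(
    params: ParameterSet,
    protocols: list[Protocol],
    end_week: int = 57,
    threshold: float = DEATH_THRESHOLD,
    n_substeps: int = DEFAULT_SUBSTEPS,
) -> list[SurvivalSummary]:
    """Run each protocol and summarize death/censoring outcomes."""
    rows = []
    for proto in protocols:
        traj = simulate(
            params, proto, end_week=end_week, threshold=threshold,
            stop_at_death=True, n_substeps=n_substeps,
        )
        rows.append(
            SurvivalSummary(
                protocol=proto.name,
                death_step=traj.death_step,
                death_week=traj.death_week,
                censored=traj.death_step is None,
            )
        )
    return rows
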