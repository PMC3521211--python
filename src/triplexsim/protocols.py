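"""Vaccination calendars.

The in vivo study administered the Triplex vaccine in 4-week cycles:
twice-weekly injections for the first two weeks followed by two weeks of
rest.  The Chronic protocol repeats this cycle for the whole observation
horizon; the Early protocol stops after the first three cycles; the
Untreated control receives no injections.  Treatment begins at week 6 of
age.

Calendars are expressed as the 8-hour time steps (counted from birth,
step 0) at which a dose of ``q`` vaccine cells is added.  Only the
relative spacing of the two weekly injections (3 then 4 days apart) is
dynamically meaningful, so each injection week uses day offsets 0 and 3
and the first injection falls on the cycle's first day.  Injections are
applied at the first 8-hour step of their scheduled day.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import STEPS_PER_DAY, STEPS_PER_WEEK

__all__ = [
    "CYCLE_DAYS",
    "Protocol",
    "build_cycle",
    "build_protocol",
    "injections_at",
]

# length of one vaccination cycle in days: 2 weeks of injections + 2 of rest
CYCLE_DAYS: int = 28
# day offsets of the four injections within a cycle (Tue/Fri of weeks 1-2)
_CYCLE_OFFSETS: tuple[int, ...] = (0, 3, 7, 10)

DEFAULT_START_WEEK: int = 6
DEFAULT_END_WEEK: int = 57
EARLY_CYCLES: int = 3


@dataclass(frozen=True)
class Protocol:
    """An injection calendar: when (8-h steps from birth) and how much."""

    name: str
    injection_steps: tuple[int, ...]
    dose_q: float

    def __post_init__(self) -> None:
        steps = self.injection_steps
        if any(s < 0 for s in steps):
            raise ValueError("injection steps must be nonnegative")
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("injection steps must be strictly increasing")
        if self.dose_q < 0:
            raise ValueError("dose_q must be nonnegative")


def build_cycle(cycle_start_day: int) -> list[int]:
    """Injection days of one 4-week cycle starting at ``cycle_start_day``.

    Two injections (3 days apart) in each of the first two weeks, then two
    weeks of rest: offsets 0, 3, 7, 10 days from the cycle start.
    """
    if cycle_start_day < 0:
        raise ValueError("cycle_start_day must be nonnegative")
    return [cycle_start_day + off for off in _CYCLE_OFFSETS]


def build_protocol(
    kind: str,
    start_week: int = DEFAULT_START_WEEK,
    end_week: int = DEFAULT_END_WEEK,
    dose_q: float = 50.0,
    custom_days: list[int] | None = None,
) -> Protocol:
    """Build a named preset or custom injection calendar.

    Parameters
    ----------
    kind
        ``"untreated"`` (no injections), ``"early"`` (three cycles from
        ``start_week``), ``"chronic"`` (cycles every 4 weeks from
        ``start_week`` until ``end_week``) or ``"custom"`` (explicit
        ``custom_days``, in days from birth).
    start_week, end_week
        Protocol window in weeks of age; cycles start at ``start_week``.
    dose_q
        Vaccine cells added per injection.
    """
    if start_week < 0:
        raise ValueError("start_week must be nonnegative")
    if end_week <= start_week:
        raise ValueError("end_week must exceed start_week")

    kind = kind.lower()
    horizon_day = end_week * 7
    if kind == "untreated":
        days: list[int] = []
    elif kind in ("early", "chronic"):
        start_day = start_week * 7
        n_cycles = EARLY_CYCLES if kind == "early" else 10**9
        days = []
        cycle = 0
        while cycle < n_cycles:
            cycle_start = start_day + cycle * CYCLE_DAYS
            if cycle_start >= horizon_day:
                break
            days.extend(d for d in build_cycle(cycle_start) if d < horizon_day)
            cycle += 1
    elif kind == "custom":
        if custom_days is None:
            raise ValueError("custom protocol requires custom_days")
        days = [int(d) for d in custom_days]
        if any(d < 0 for d in days):
            raise ValueError("custom_days must be nonnegative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("custom_days must be sorted and unique")
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")

    steps = tuple(d * STEPS_PER_DAY for d in days)
    return Protocol(name=kind, injection_steps=steps, dose_q=float(dose_q))


def injections_at(protocol: Protocol, step: int) -> float:
    """Vaccine cells added at ``step`` (dose_q on scheduled steps, else 0)."""
    return protocol.dose_q if step in set(protocol.injection_steps) else 0.0
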