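"""Dosing histories: bolus and piecewise-constant maintenance-rate events.

Times are hours since the first bolus (the case-level normalization applied by
:mod:`mgpk.io`). A schedule is an ordered event list plus a treatment end; the
maintenance rate is piecewise constant between ``rate_change`` events and zero
after ``treatment_end``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional

import numpy as np

__all__ = ["DosingEvent", "DosingSchedule", "ScheduleError"]

#: default bolus administration time (h); 20 minutes
DEFAULT_BOLUS_DURATION = 1.0 / 3.0


class ScheduleError(ValueError):
    """Raised for malformed or un-normalized dosing schedules."""


@dataclass(frozen=True)
class DosingEvent:
    """One dosing event on the time-since-first-bolus axis.

    ``bolus`` carries ``dose`` (g) and ``bolus_duration`` (h; 0 means an
    instantaneous IV push). ``rate_change`` carries the new maintenance
    ``rate`` (g/h); ``stop`` is shorthand for a rate change to 0.
    """

    time: float
    kind: Literal["bolus", "rate_change", "stop"]
    dose: Optional[float] = None
    rate: Optional[float] = None
    bolus_duration: float = DEFAULT_BOLUS_DURATION

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ScheduleError("event time must be >= 0")
        if self.kind == "bolus":
            # dose 0 is allowed as a pure time anchor (e.g. synthetic tests)
            if self.dose is None or self.dose < 0:
                raise ScheduleError("bolus requires dose >= 0")
            if self.bolus_duration < 0:
                raise ScheduleError("bolus_duration must be >= 0")
        elif self.kind == "rate_change":
            if self.rate is None or self.rate < 0:
                raise ScheduleError("rate_change requires rate >= 0")
        elif self.kind == "stop":
            object.__setattr__(self, "rate", 0.0)
        else:
            raise ScheduleError(f"unknown event kind {self.kind!r}")

    @property
    def sort_key(self) -> tuple[float, int]:
        # deterministic tie-break: bolus before rate changes at equal time
        return (self.time, 0 if self.kind == "bolus" else 1)


@dataclass(frozen=True)
class DosingSchedule:
    """Ordered dosing events plus treatment end (hours since first bolus)."""

    events: tuple[DosingEvent, ...]
    treatment_end: float

    def __post_init__(self) -> None:
        if not self.events:
            raise ScheduleError("schedule must contain at least one event")
        keys = [e.sort_key for e in self.events]
        if keys != sorted(keys):
            raise ScheduleError("events must be sorted by (time, bolus-first)")
        if not any(e.kind == "bolus" for e in self.events):
            raise ScheduleError("schedule must contain a bolus (start of treatment)")
        if sum(1 for e in self.events if e.kind == "bolus" and e.time == self.events[0].time) > 1:
            raise ScheduleError("ambiguous schedule: multiple boluses at the start time")
        if self.treatment_end < max(e.time for e in self.events):
            raise ScheduleError("treatment_end must be >= last event time")

    @property
    def is_normalized(self) -> bool:
        """True when anchored to the first bolus: first event is a bolus at 0."""
        first = self.events[0]
        return first.kind == "bolus" and first.time == 0.0

    @classmethod
    def from_events(cls, events: Iterable[DosingEvent], treatment_end: float) -> "DosingSchedule":
        return cls(tuple(sorted(events, key=lambda e: e.sort_key)), float(treatment_end))

    @property
    def boluses(self) -> tuple[DosingEvent, ...]:
        return tuple(e for e in self.events if e.kind == "bolus")

    @property
    def maintenance_start(self) -> Optional[float]:
        """Time of the first rate change (start of maintenance), or None."""
        for e in self.events:
            if e.kind in ("rate_change", "stop"):
                return e.time
        return None

    def rate_segments(self) -> list[tuple[float, float, float]]:
        """Maintenance rate as (start, end, rate g/h) segments up to treatment_end."""
        changes = [e for e in self.events if e.kind in ("rate_change", "stop")]
        segments: list[tuple[float, float, float]] = []
        for i, e in enumerate(changes):
            end = changes[i + 1].time if i + 1 < len(changes) else self.treatment_end
            if end > e.time:
                segments.append((e.time, end, float(e.rate)))
        return segments

    def rate_at(self, t: float) -> float:
        """Maintenance rate (g/h) in force at time t (0 after treatment_end;
        at exactly treatment_end the still-running rate is attributed)."""
        if t > self.treatment_end:
            return 0.0
        rate = 0.0
        for e in self.events:
            if e.kind in ("rate_change", "stop") and e.time <= t:
                rate = float(e.rate)
        return rate

    def rate_deltas(self) -> list[tuple[float, float]]:
        """Maintenance history as (time, rate increment g/h) steps.

        Includes the implicit stop at ``treatment_end``; the running rate is
        the cumulative sum of increments. This is the superposition-friendly
        view: each increment is a constant infusion running from its start
        time onward.
        """
        deltas: list[tuple[float, float]] = []
        current = 0.0
        for e in self.events:
            if e.kind in ("rate_change", "stop"):
                delta = float(e.rate) - current
                if delta != 0.0:
                    deltas.append((e.time, delta))
                current = float(e.rate)
        if current != 0.0:
            deltas.append((self.treatment_end, -current))
        return deltas

    def extended(self, treatment_end: float) -> "DosingSchedule":
        return replace(self, treatment_end=float(treatment_end))


def total_maintenance_dose(schedule: DosingSchedule) -> float:
    """Grams of MgSO4 delivered by the maintenance infusion."""
    return float(sum((end - start) * rate for start, end, rate in schedule.rate_segments()))
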