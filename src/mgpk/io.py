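"""Cohort data model and tidy-CSV ingestion of dosing histories.

A cohort is exchanged as three UTF-8 CSVs with headers:

* covariates:   ``case_id, weight_kg, creatinine_umol_L[, gestational_age_weeks]``
* dosing:       ``case_id, time, kind, dose_g, rate_g_per_h[, bolus_duration_h]``
* observations: ``case_id, time, conc_mmol_L``

``time`` is either hours since first bolus (``time_mode="hours"``) or an ISO
8601 clock timestamp (``time_mode="clock"``); clock times are normalized to
hours since the case's first bolus on ingestion.

Cases violating the eligibility invariants (positive weight and creatinine on
record, a well-defined bolus start, at least two magnesium observations) are
not silently dropped: :func:`read_cohort` returns them in a rejection list
with the reason, so exclusion flow counts can be reported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .dosing import DEFAULT_BOLUS_DURATION, DosingEvent, DosingSchedule, ScheduleError

__all__ = [
    "Observation",
    "CaseRecord",
    "Rejection",
    "CohortDataset",
    "read_cohort",
    "write_cohort",
    "normalize_times",
    "weighted_mean_rate",
]

logger = logging.getLogger(__name__)

REASON_NO_WEIGHT = "no recent body weight measurement"
REASON_NO_CREATININE = "no recent creatinine measurement"
REASON_NO_BOLUS = "no well-defined start of treatment"
REASON_ONE_OBSERVATION = "only one measurement of magnesium"


@dataclass(frozen=True)
class Observation:
    """One serum magnesium measurement (hours since first bolus, mmol/L)."""

    time: float
    conc: float
    aberrant: bool = False

    def __post_init__(self) -> None:
        if self.conc <= 0:
            raise ValueError("conc must be positive")


@dataclass(frozen=True)
class CaseRecord:
    """One treated pregnancy: covariates, dosing schedule, observations."""

    case_id: str
    weight: float  # kg
    creatinine: float  # µmol/L
    schedule: DosingSchedule
    observations: tuple[Observation, ...]
    gestational_age: Optional[float] = None  # weeks (decimal)

    def __post_init__(self) -> None:
        times = [o.time for o in self.observations]
        if any(t < 0 for t in times):
            raise ValueError("observation times must be >= 0")
        if any(b >= a for a, b in zip(times[1:], times[:-1])):
            raise ValueError("observation times must be strictly increasing")

    @property
    def duration(self) -> float:
        """Treatment duration in hours."""
        return self.schedule.treatment_end

    def with_observations(self, observations: Sequence[Observation]) -> "CaseRecord":
        return replace(self, observations=tuple(observations))


@dataclass(frozen=True)
class Rejection:
    case_id: str
    reason: str


@dataclass
class CohortDataset:
    """Accepted cases plus the rejection list from ingestion/eligibility."""

    cases: list[CaseRecord] = field(default_factory=list)
    rejected: list[Rejection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cases)

    def case(self, case_id: str) -> CaseRecord:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)


def _parse_time_columns(
    dosing: pd.Series, observations: pd.Series, time_mode: str
) -> tuple[pd.Series, pd.Series]:
    if time_mode == "hours":
        return (
            pd.to_numeric(dosing, errors="raise").astype(float),
            pd.to_numeric(observations, errors="raise").astype(float),
        )
    if time_mode == "clock":
        td = pd.to_datetime(dosing, errors="raise")
        to = pd.to_datetime(observations, errors="raise")
        # shared arbitrary origin; the per-case shift to first bolus follows
        origin = min(td.min(), to.min())
        return (
            (td - origin).dt.total_seconds() / 3600.0,
            (to - origin).dt.total_seconds() / 3600.0,
        )
    raise ValueError(f"time_mode must be 'hours' or 'clock', got {time_mode!r}")


def read_cohort(
    dosing_file: str | Path,
    observation_file: str | Path,
    covariate_file: str | Path,
    time_mode: str = "hours",
) -> CohortDataset:
    """Read and validate the three cohort CSVs.

    Returns a dataset of accepted, time-normalized cases plus rejections with
    reasons; malformed rows raise with the offending row number, unknown
    case_id cross-references raise KeyError.
    """
    cov = pd.read_csv(covariate_file, dtype={"case_id": str})
    dos = pd.read_csv(dosing_file, dtype={"case_id": str})
    obs = pd.read_csv(observation_file, dtype={"case_id": str})

    for name, df, required in (
        ("covariates", cov, {"case_id", "weight_kg", "creatinine_umol_L"}),
        ("dosing", dos, {"case_id", "time", "kind"}),
        ("observations", obs, {"case_id", "time", "conc_mmol_L"}),
    ):
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{name} file missing columns: {sorted(missing)}")

    known = set(cov["case_id"])
    for name, df in (("dosing", dos), ("observations", obs)):
        unknown = set(df["case_id"]) - known
        if unknown:
            raise KeyError(f"{name} file references unknown case_id(s): {sorted(unknown)}")

    dos_t, obs_t = _parse_time_columns(dos["time"], obs["time"], time_mode)
    dos = dos.assign(time=dos_t)
    obs = obs.assign(time=obs_t)

    dataset = CohortDataset()
    for row in cov.itertuples(index=False):
        cid = row.case_id
        weight = getattr(row, "weight_kg", np.nan)
        creat = getattr(row, "creatinine_umol_L", np.nan)
        ga = getattr(row, "gestational_age_weeks", np.nan)
        if pd.isna(weight) or weight <= 0:
            dataset.rejected.append(Rejection(cid, REASON_NO_WEIGHT))
            continue
        if pd.isna(creat) or creat <= 0:
            dataset.rejected.append(Rejection(cid, REASON_NO_CREATININE))
            continue

        d = dos[dos["case_id"] == cid]
        events = []
        for i, r in enumerate(d.itertuples(index=False)):
            try:
                if r.kind == "bolus":
                    dur = getattr(r, "bolus_duration_h", np.nan)
                    events.append(
                        DosingEvent(
                            time=r.time,
                            kind="bolus",
                            dose=float(r.dose_g),
                            bolus_duration=DEFAULT_BOLUS_DURATION if pd.isna(dur) else float(dur),
                        )
                    )
                elif r.kind in ("rate_change", "stop"):
                    rate = 0.0 if r.kind == "stop" else float(r.rate_g_per_h)
                    events.append(DosingEvent(time=r.time, kind="rate_change", rate=rate))
                else:
                    raise ScheduleError(f"unknown event kind {r.kind!r}")
            except (ScheduleError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed dosing row {i} for case {cid}: {exc}") from exc
        if not any(e.kind == "bolus" for e in events):
            dataset.rejected.append(Rejection(cid, REASON_NO_BOLUS))
            continue

        o = obs[obs["case_id"] == cid].sort_values("time")
        if len(o) < 2:
            dataset.rejected.append(Rejection(cid, REASON_ONE_OBSERVATION))
            continue

        bolus_t0 = min(e.time for e in events if e.kind == "bolus")
        events = [replace(e, time=e.time - bolus_t0) for e in events]
        events.sort(key=lambda e: e.sort_key)
        last_t = max(
            max(e.time for e in events), float(o["time"].max()) - bolus_t0
        )
        aberrant_col = o["aberrant"].astype(bool) if "aberrant" in o.columns else [False] * len(o)
        observations = tuple(
            Observation(time=t - bolus_t0, conc=float(c), aberrant=bool(a))
            for t, c, a in zip(o["time"], o["conc_mmol_L"], aberrant_col)
            if t - bolus_t0 >= 0
        )
        dropped = len(o) - len(observations)
        if dropped:
            logger.warning("case %s: dropped %d observation(s) before first bolus", cid, dropped)
        if len(observations) < 2:
            dataset.rejected.append(Rejection(cid, REASON_ONE_OBSERVATION))
            continue

        schedule = DosingSchedule.from_events(events, treatment_end=last_t)
        dataset.cases.append(
            CaseRecord(
                case_id=cid,
                weight=float(weight),
                creatinine=float(creat),
                gestational_age=None if pd.isna(ga) else float(ga),
                schedule=schedule,
                observations=observations,
            )
        )
    return dataset


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tidy CSVs (normalized hours). Deterministic formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov_rows, dos_rows, obs_rows = [], [], []
    for c in dataset.cases:
        cov_rows.append(
            {
                "case_id": c.case_id,
                "weight_kg": c.weight,
                "creatinine_umol_L": c.creatinine,
                "gestational_age_weeks": c.gestational_age,
            }
        )
        for e in c.schedule.events:
            dos_rows.append(
                {
                    "case_id": c.case_id,
                    "time": e.time,
                    "kind": e.kind,
                    "dose_g": e.dose,
                    "rate_g_per_h": e.rate,
                    "bolus_duration_h": e.bolus_duration if e.kind == "bolus" else None,
                }
            )
        for o in c.observations:
            obs_rows.append(
                {"case_id": c.case_id, "time": o.time, "conc_mmol_L": o.conc, "aberrant": o.aberrant}
            )
    paths = {
        "covariates": out / "covariates.csv",
        "dosing": out / "dosing.csv",
        "observations": out / "observations.csv",
    }
    pd.DataFrame(cov_rows).to_csv(paths["covariates"], index=False, float_format="%.10g")
    pd.DataFrame(dos_rows).to_csv(paths["dosing"], index=False, float_format="%.10g")
    pd.DataFrame(obs_rows).to_csv(paths["observations"], index=False, float_format="%.10g")
    return paths


def normalize_times(case: CaseRecord) -> CaseRecord:
    """Shift all times so the first bolus is at 0; drop pre-bolus observations.

    Idempotent: a case already anchored at 0 is returned unchanged.
    """
    bolus_t0 = min(e.time for e in case.schedule.events if e.kind == "bolus")
    if bolus_t0 == 0.0:
        return case
    events = [replace(e, time=e.time - bolus_t0) for e in case.schedule.events]
    observations = tuple(
        replace(o, time=o.time - bolus_t0) for o in case.observations if o.time >= bolus_t0
    )
    dropped = len(case.observations) - len(observations)
    if dropped:
        logger.warning(
            "case %s: dropped %d observation(s) before first bolus", case.case_id, dropped
        )
    schedule = DosingSchedule.from_events(events, case.schedule.treatment_end - bolus_t0)
    return replace(case, schedule=schedule, observations=observations)


def weighted_mean_rate(schedule: DosingSchedule) -> float:
    """Time-weighted mean maintenance infusion rate (g/h), bolus excluded,
    from the start of maintenance to treatment end."""
    start = schedule.maintenance_start
    if start is None or schedule.treatment_end <= start:
        raise ValueError("schedule has no maintenance period")
    total = sum((end - s) * r for s, end, r in schedule.rate_segments())
    return float(total / (schedule.treatment_end - start))
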