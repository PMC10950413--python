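"""Synthetic preeclampsia cohorts under the Zuspan protocol with titration.

The generator emulates the study conditions of a guideline-driven magnesium
sulfate course: a 4 g IV bolus, 1 g/h maintenance, a serum magnesium check
1 h after the start of maintenance and after every rate change, and a
0.25 g/h rate increase whenever the checked (measured, i.e. error-corrupted)
concentration is below the 2.0 mmol/L target — the closed loop a ward
actually runs, in which noisy measurements drive titration decisions.
Rates only ever increase, up to a protocol cap.

Demographics are sampled from log-normal marginals solved to match the
cohort quartiles (weight median 84 kg, IQR 73–95; creatinine median
57 µmol/L, IQR 51–69; treatment duration median 29.6 h, IQR 23.7–46.0).
Measurements carry a proportional + additive assay error and, with small
probability, a spurious high outlier reading — emulating the occasional
erroneous laboratory value that a screening rule must catch downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dosing import DosingEvent, DosingSchedule
from .engine import concentration_at
from .io import CaseRecord, CohortDataset, Observation
from .params import CovariateModel, PKParameters, default_covariate_model, default_parameters, individualize

__all__ = [
    "ProtocolConfig",
    "ErrorModel",
    "DemographicsConfig",
    "Subject",
    "sample_demographics",
    "simulate_case",
    "simulate_cohort",
]

#: z-score of the 75th percentile of the standard normal
_Z75 = stats.norm.ppf(0.75)


@dataclass(frozen=True)
class ProtocolConfig:
    """Zuspan regimen with stepwise titration.

    All times in hours, doses in g, rates in g/h, concentrations in mmol/L.
    ``max_rate`` is the protocol ceiling on the maintenance rate; titration
    only ever increases the rate, and stops at the ceiling.
    """

    bolus_dose: float = 4.0
    bolus_duration: float = 1.0 / 3.0  # 20 min administration
    initial_rate: float = 1.0
    titration_step: float = 0.25
    titration_threshold: float = 2.0
    check_delay: float = 1.0
    max_rate: float = 2.0
    extra_sample_times: tuple[float, ...] = (4.0, 8.0, 12.0, 18.0, 24.0)
    late_sample_interval: float = 12.0
    max_duration: float = 60.0
    postpartum_continue: float = 24.0  # guideline recommendation; informational

    def __post_init__(self) -> None:
        for name in ("bolus_dose", "initial_rate", "titration_step", "titration_threshold",
                     "check_delay", "max_rate", "late_sample_interval", "max_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bolus_duration < 0:
            raise ValueError("bolus_duration must be >= 0")

    def sample_times(self, treatment_end: float) -> list[float]:
        times = [t for t in self.extra_sample_times if t <= treatment_end]
        t = max(self.extra_sample_times, default=0.0) + self.late_sample_interval
        while t <= treatment_end:
            times.append(t)
            t += self.late_sample_interval
        return times


@dataclass(frozen=True)
class ErrorModel:
    """Residual assay-error model plus spurious-outlier injection.

    measured = true · (1 + N(0, cv)) + N(0, sd) + bias + weight_bias·weight,
    replaced with probability ``outlier_prob`` by U(outlier_low, outlier_high).
    The bias terms default to 0 and exist for error-recovery experiments.
    """

    proportional_cv: float = 0.07
    additive_sd: float = 0.05
    outlier_prob: float = 0.01
    outlier_low: float = 3.5
    outlier_high: float = 7.5
    additive_bias: float = 0.0
    weight_bias_slope: float = 0.0  # mmol/L per kg

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("error SDs must be >= 0")
        if not (0.0 <= self.outlier_prob <= 1.0):
            raise ValueError("outlier_prob must be in [0, 1]")
        if self.outlier_high < self.outlier_low:
            raise ValueError("outlier bounds must be ordered")

    def corrupt(self, true_conc: float, weight: float, rng: np.random.Generator) -> float:
        if self.outlier_prob > 0 and rng.random() < self.outlier_prob:
            return float(rng.uniform(self.outlier_low, self.outlier_high))
        measured = true_conc
        if self.proportional_cv > 0:
            measured *= 1.0 + rng.normal(0.0, self.proportional_cv)
        if self.additive_sd > 0:
            measured += rng.normal(0.0, self.additive_sd)
        measured += self.additive_bias + self.weight_bias_slope * weight
        return float(max(measured, 0.01))


def _lognormal_from_quartiles(q1: float, median: float, q3: float) -> tuple[float, float, float]:
    """(mu, sigma_low, sigma_high) of a two-piece log-normal hitting all three
    quartiles exactly: log-sd sigma_low below the median, sigma_high above."""
    if not (0 < q1 < median < q3):
        raise ValueError("quartiles must be strictly increasing and positive")
    return (
        math.log(median),
        math.log(median / q1) / _Z75,
        math.log(q3 / median) / _Z75,
    )


def _split_lognormal(z: np.ndarray, mu: float, s_lo: float, s_hi: float) -> np.ndarray:
    return np.exp(mu + np.where(z < 0.0, s_lo, s_hi) * z)


@dataclass(frozen=True)
class DemographicsConfig:
    """Quartile-parameterised two-piece log-normal marginals for the cohort.

    Defaults reproduce the validation cohort's summary demographics. Weight
    and creatinine are sampled independently unless ``weight_creatinine_rho``
    sets a Gaussian-copula correlation.
    """

    weight_quartiles: tuple[float, float, float] = (73.0, 84.0, 95.0)
    creatinine_quartiles: tuple[float, float, float] = (51.0, 57.0, 69.0)
    gestational_age_quartiles: tuple[float, float, float] = (33.14, 35.71, 38.43)
    duration_quartiles: tuple[float, float, float] = (23.7, 29.6, 46.0)
    duration_floor: float = 6.0
    weight_creatinine_rho: float = 0.0

    def __post_init__(self) -> None:
        for q in (self.weight_quartiles, self.creatinine_quartiles,
                  self.gestational_age_quartiles, self.duration_quartiles):
            _lognormal_from_quartiles(*q)  # validates ordering
        if not (-1.0 < self.weight_creatinine_rho < 1.0):
            raise ValueError("copula correlation must be in (-1, 1)")


@dataclass(frozen=True)
class Subject:
    weight: float
    creatinine: float
    gestational_age: float
    duration: float


def sample_demographics(
    n: int,
    rng: np.random.Generator,
    config: DemographicsConfig | None = None,
) -> list[Subject]:
    """Draw n subjects with log-normal marginals matching the config quartiles."""
    if n < 0:
        raise ValueError("n must be >= 0")
    config = config or DemographicsConfig()
    qw = _lognormal_from_quartiles(*config.weight_quartiles)
    qc = _lognormal_from_quartiles(*config.creatinine_quartiles)
    qg = _lognormal_from_quartiles(*config.gestational_age_quartiles)
    qd = _lognormal_from_quartiles(*config.duration_quartiles)

    zw = rng.standard_normal(n)
    zc_ind = rng.standard_normal(n)
    rho = config.weight_creatinine_rho
    zc = rho * zw + math.sqrt(1.0 - rho * rho) * zc_ind
    weight = _split_lognormal(zw, *qw)
    creat = _split_lognormal(zc, *qc)
    ga = _split_lognormal(rng.standard_normal(n), *qg)
    dur = _split_lognormal(rng.standard_normal(n), *qd)
    dur = np.clip(dur, config.duration_floor, None)
    return [
        Subject(weight=float(w), creatinine=float(c), gestational_age=float(g), duration=float(d))
        for w, c, g, d in zip(weight, creat, ga, dur)
    ]


def _apply_bsv(params: PKParameters, bsv_cv: float, rng: np.random.Generator) -> PKParameters:
    """Log-normal between-subject variability on CL and V1 (off by default)."""
    if bsv_cv <= 0:
        return params
    eta = rng.normal(0.0, bsv_cv, size=2)
    return replace(params, CL=params.CL * math.exp(eta[0]), V1=params.V1 * math.exp(eta[1]))


def simulate_case(
    subject: Subject,
    protocol: ProtocolConfig,
    typical: PKParameters,
    covmodel: CovariateModel,
    error: ErrorModel,
    rng: np.random.Generator,
    case_id: str = "sim-001",
    bsv_cv: float = 0.0,
) -> CaseRecord:
    """Simulate one case through the titration closed loop.

    True concentrations come from the individualized PK engine over the
    schedule built so far; the *measured* (error-corrupted) value at each
    check drives the titration decision, as on the ward.
    """
    params = _apply_bsv(individualize(typical, covmodel, subject.weight, subject.creatinine),
                        bsv_cv, rng)
    end = min(subject.duration, protocol.max_duration)
    events: list[DosingEvent] = [
        DosingEvent(time=0.0, kind="bolus", dose=protocol.bolus_dose,
                    bolus_duration=protocol.bolus_duration),
        DosingEvent(time=0.0, kind="rate_change", rate=protocol.initial_rate),
    ]
    rate = protocol.initial_rate

    # merge titration checks and scheduled samples into one ordered agenda
    agenda: list[tuple[float, bool]] = [(protocol.check_delay, True)]
    agenda += [(t, False) for t in protocol.sample_times(end)]
    observations: list[Observation] = []
    seen_times: set[float] = set()

    while agenda:
        agenda.sort()
        t, is_check = agenda.pop(0)
        if t > end:
            continue
        schedule = DosingSchedule.from_events(events, treatment_end=end)
        if t in seen_times:
            measured = next(o.conc for o in observations if o.time == t)
        else:
            true = float(concentration_at(schedule, params, np.array([t]))[0])
            measured = error.corrupt(true, subject.weight, rng)
            observations.append(Observation(time=t, conc=measured))
            seen_times.add(t)
        if is_check and measured < protocol.titration_threshold and rate < protocol.max_rate:
            rate = min(rate + protocol.titration_step, protocol.max_rate)
            events.append(DosingEvent(time=t, kind="rate_change", rate=rate))
            nxt = t + protocol.check_delay
            if nxt <= end:
                agenda.append((nxt, True))

    observations.sort(key=lambda o: o.time)
    schedule = DosingSchedule.from_events(events, treatment_end=end)
    return CaseRecord(
        case_id=case_id,
        weight=subject.weight,
        creatinine=subject.creatinine,
        gestational_age=subject.gestational_age,
        schedule=schedule,
        observations=tuple(observations),
    )


def simulate_cohort(
    n: int,
    seed: int,
    protocol: ProtocolConfig | None = None,
    typical: PKParameters | None = None,
    covmodel: CovariateModel | None = None,
    error: ErrorModel | None = None,
    demographics: DemographicsConfig | None = None,
    bsv_cv: float = 0.0,
) -> CohortDataset:
    """Simulate a cohort of n cases; per-case seeds derive deterministically
    from the master seed, so equal seeds give identical cohorts."""
    protocol = protocol or ProtocolConfig()
    typical = typical or default_parameters()
    covmodel = covmodel or default_covariate_model()
    error = error or ErrorModel()
    ss = np.random.SeedSequence(seed)
    demo_rng = np.random.default_rng(ss.spawn(1)[0])
    subjects = sample_demographics(n, demo_rng, demographics)
    case_seeds = ss.spawn(n + 1)[1:]
    dataset = CohortDataset()
    width = max(3, len(str(n)))
    for i, (subject, cs) in enumerate(zip(subjects, case_seeds), start=1):
        rng = np.random.default_rng(cs)
        dataset.cases.append(
            simulate_case(
                subject, protocol, typical, covmodel, error, rng,
                case_id=f"sim-{i:0{width}d}", bsv_cv=bsv_cv,
            )
        )
    return dataset
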