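"""Closed-form two-compartment IV-infusion engine with dosing superposition.

The disposition model is the standard mammillary two-compartment system with
elimination from the central compartment:

    dA1/dt = in(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - k21 A2,          C(t) = baseline + A1(t) / V1

with k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 and hybrid rate constants α > β > 0,
the roots of s² + (k10+k12+k21)s + k10·k21 = 0.

For a constant infusion at rate R (mmol/h) started at 0 and still running,

    C_drug(t) = (R/V1) [ (A/α)(1 - e^{-αt}) + (B/β)(1 - e^{-βt}) ],
    A = (α - k21)/(α - β),  B = (k21 - β)/(α - β),

which tends to R/CL as t → ∞. Because the system is linear, an arbitrary
piecewise-constant dosing history is the superposition of such responses, one
per rate *increment* (rate changes and stops are negative increments; a bolus
is a short infusion of configurable duration, or an impulse D/V1·(A e^{-αt} +
B e^{-βt}) in the zero-duration limit). The endogenous baseline is an additive
constant on top of the drug-attributable concentration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dosing import DosingSchedule
from .params import PKParameters

__all__ = [
    "DegenerateModelError",
    "hybrid_constants",
    "infusion_response",
    "predict_profile",
    "concentration_at",
    "steady_state",
    "time_to_threshold",
    "ConcentrationProfile",
    "DEFAULT_RESOLUTION",
]

#: default grid resolution, 5 minutes in hours
DEFAULT_RESOLUTION = 1.0 / 12.0


class DegenerateModelError(ValueError):
    """Q = 0 collapses the model to one compartment; hybrid constants undefined."""


def hybrid_constants(params: PKParameters) -> tuple[float, float]:
    """Hybrid rate constants (α, β), α > β > 0, of the two-compartment system.

    Roots of s² + (k10+k12+k21)s + k10·k21 = 0, computed in the numerically
    stable form β = product / α to avoid cancellation.
    """
    if params.Q == 0:
        raise DegenerateModelError("Q = 0: use the one-compartment limit")
    k10, k12, k21 = params.k10, params.k12, params.k21
    s = k10 + k12 + k21
    p = k10 * k21
    disc = math.sqrt(s * s - 4.0 * p)
    alpha = 0.5 * (s + disc)
    beta = p / alpha
    return alpha, beta


def _macro_coefficients(params: PKParameters) -> tuple[float, float, float, float]:
    """(α, β, A, B) with A + B = 1 for the unit-bolus biexponential."""
    alpha, beta = hybrid_constants(params)
    k21 = params.k21
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)
    return alpha, beta, A, B


def _unit_infusion(t: np.ndarray, params: PKParameters) -> np.ndarray:
    """Central concentration for a 1 mmol/h infusion running since time 0.

    Zero for t < 0 (superposition convenience)."""
    alpha, beta, A, B = _macro_coefficients(params)
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t, 0.0)
    out = (A / alpha * -np.expm1(-alpha * tp) + B / beta * -np.expm1(-beta * tp)) / params.V1
    return np.where(t < 0.0, 0.0, out)


def _unit_bolus(t: np.ndarray, params: PKParameters) -> np.ndarray:
    """Central concentration for an instantaneous 1 mmol bolus at time 0."""
    alpha, beta, A, B = _macro_coefficients(params)
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t, 0.0)
    out = (A * np.exp(-alpha * tp) + B * np.exp(-beta * tp)) / params.V1
    return np.where(t < 0.0, 0.0, out)


def infusion_response(rate: float, t_since_start, params: PKParameters):
    """Drug concentration (mmol/L) of a constant infusion of `rate` mmol/h
    started at 0 and still running at `t_since_start` hours.

    Monotone non-decreasing in t with limit rate/CL.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    t = np.asarray(t_since_start, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_start must be >= 0")
    out = rate * _unit_infusion(t, params)
    return float(out) if np.isscalar(t_since_start) else out


def concentration_at(schedule: DosingSchedule, params: PKParameters, times) -> np.ndarray:
    """Total serum concentration (baseline + drug) at arbitrary times (h).

    Superposes one running-infusion response per maintenance-rate increment
    and per bolus (short infusion, or impulse when bolus_duration == 0).
    Dose units: labelled grams are converted with ``params.dose_to_amount``.
    """
    if not schedule.is_normalized:
        from .dosing import ScheduleError

        raise ScheduleError("schedule must be normalized (first bolus at t=0) before prediction")
    t = np.asarray(times, dtype=float)
    conc = np.full(t.shape, params.baseline, dtype=float)
    f = params.dose_to_amount
    for start, delta in schedule.rate_deltas():
        conc = conc + delta * f * _unit_infusion(t - start, params)
    for ev in schedule.boluses:
        amount = ev.dose * f  # mmol
        if ev.bolus_duration > 0:
            rate = amount / ev.bolus_duration
            conc = conc + rate * (
                _unit_infusion(t - ev.time, params)
                - _unit_infusion(t - ev.time - ev.bolus_duration, params)
            )
        else:
            conc = conc + amount * _unit_bolus(t - ev.time, params)
    return conc


@dataclass(frozen=True)
class ConcentrationProfile:
    """Predicted total serum magnesium on a uniform time grid."""

    times: np.ndarray  # hours, uniform, starts at 0
    conc: np.ndarray  # mmol/L
    resolution: float  # hours

    def __post_init__(self) -> None:
        if self.times.shape != self.conc.shape or self.times.ndim != 1:
            raise ValueError("times and conc must be 1-d arrays of equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, self.resolution, rtol=1e-9, atol=1e-12):
                raise ValueError("grid must be strictly increasing and uniform")

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def nearest_index(self, t: float) -> int:
        return int(round(t / self.resolution))

    def to_frame(self, case_id: str | None = None):
        import pandas as pd

        df = pd.DataFrame({"time_h": self.times, "conc_mmol_L": self.conc})
        if case_id is not None:
            df.insert(0, "case_id", case_id)
        return df


def predict_profile(
    schedule: DosingSchedule,
    params: PKParameters,
    resolution: float = DEFAULT_RESOLUTION,
    horizon: float | None = None,
) -> ConcentrationProfile:
    """Concentration table on a uniform grid from 0 to `horizon` (default
    treatment end), taking all rate changes into account."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if horizon is None:
        horizon = schedule.treatment_end
    n = int(round(horizon / resolution))
    times = np.arange(n + 1) * resolution
    conc = concentration_at(schedule, params, times)
    return ConcentrationProfile(times=times, conc=conc, resolution=resolution)


def steady_state(rate: float, params: PKParameters) -> float:
    """Plateau concentration of a constant maintenance infusion (g/h):
    baseline + rate·dose_to_amount/CL."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return params.baseline + rate * params.dose_to_amount / params.CL


def time_to_threshold(profile: ConcentrationProfile, threshold: float):
    """First grid time with concentration strictly above `threshold`, else None.

    Evaluated on the grid (no interpolation) for determinism.
    """
    above = profile.conc > threshold
    if not np.any(above):
        return None
    return float(profile.times[int(np.argmax(above))])
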