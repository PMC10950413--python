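"""External-validation statistics: prediction error, bias, calibration,
treatment-period summaries, and aberrant/toxicity screening.

Measured concentrations are time-matched to the nearest point of the
predicted grid; the prediction error is the *signed* difference
measured − predicted on the concentration scale (mmol/L), so a negative mean
means the model overestimates. Observations are binned into four treatment
periods reflecting the shape of a Zuspan course — post-bolus peak, trough,
approach to steady state, extended treatment: early [0, 4) h, intermediate
[4, 17) h, late [17, 25) h, extended ≥ 25 h.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .engine import ConcentrationProfile
from .io import CaseRecord, CohortDataset, Observation

__all__ = [
    "PERIOD_LABELS",
    "period_bin",
    "MatchedPair",
    "match_predictions",
    "match_cohort",
    "mean_prediction_error",
    "bias_regression",
    "calibration_table",
    "calibration_slope",
    "period_summary",
    "flag_aberrant",
    "flag_cohort",
    "screen_toxicity",
]

PERIOD_LABELS = ("early", "intermediate", "late", "extended")
_PERIOD_EDGES = (4.0, 17.0, 25.0)  # half-open upper edges of the first three bins


def period_bin(time: float) -> str:
    """Treatment-period label: early [0,4), intermediate [4,17), late [17,25),
    extended [25, ∞) hours since first bolus."""
    if time < 0:
        raise ValueError("time must be >= 0")
    for label, edge in zip(PERIOD_LABELS, _PERIOD_EDGES):
        if time < edge:
            return label
    return "extended"


@dataclass(frozen=True)
class MatchedPair:
    """One observation time-matched to its model prediction."""

    case_id: str
    time: float
    measured: float
    predicted: float

    @property
    def error(self) -> float:
        """Signed prediction error (mmol/L); negative = model overestimates."""
        return self.measured - self.predicted

    @property
    def period(self) -> str:
        return period_bin(self.time)


def match_predictions(
    profile: ConcentrationProfile,
    observations: Sequence[Observation],
    case_id: str = "",
) -> list[MatchedPair]:
    """Match each non-aberrant observation to the nearest grid prediction.

    Observations beyond the profile horizon (by more than half a grid step)
    are dropped.
    """
    pairs: list[MatchedPair] = []
    for obs in observations:
        if obs.aberrant:
            continue
        if obs.time > profile.horizon + profile.resolution / 2.0:
            continue
        idx = min(profile.nearest_index(obs.time), len(profile.times) - 1)
        pairs.append(
            MatchedPair(
                case_id=case_id,
                time=obs.time,
                measured=obs.conc,
                predicted=float(profile.conc[idx]),
            )
        )
    return pairs


def match_cohort(
    dataset: CohortDataset,
    profiles: dict[str, ConcentrationProfile],
) -> list[MatchedPair]:
    pairs: list[MatchedPair] = []
    for case in dataset.cases:
        pairs.extend(match_predictions(profiles[case.case_id], case.observations, case.case_id))
    return pairs


def pairs_frame(pairs: Sequence[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [p.case_id for p in pairs],
            "time_h": [p.time for p in pairs],
            "measured_mmol_L": [p.measured for p in pairs],
            "predicted_mmol_L": [p.predicted for p in pairs],
            "error_mmol_L": [p.error for p in pairs],
            "period": [p.period for p in pairs],
        }
    )


def mean_prediction_error(
    pairs: Sequence[MatchedPair],
    level: float = 0.95,
    cluster_by_case: bool = False,
) -> tuple[float, tuple[float, float]]:
    """Mean signed prediction error with a Student-t confidence interval.

    By default all pairs are pooled (cases contribute one row per
    measurement). ``cluster_by_case=True`` instead computes a cluster-robust
    standard error of the pooled mean with case-level clusters, for
    sensitivity to within-case correlation.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs")
    errors = np.array([p.error for p in pairs], dtype=float)
    mean = float(errors.mean())
    n = len(errors)
    if cluster_by_case:
        cases = np.array([p.case_id for p in pairs])
        labels = np.unique(cases)
        g = len(labels)
        if g < 2:
            raise ValueError("clustered CI needs at least 2 cases")
        # cluster-sum sandwich variance of the pooled mean
        sums = np.array([np.sum(errors[cases == c] - mean) for c in labels])
        var = g / (g - 1) * float(np.sum(sums**2)) / n**2
        se, df = math.sqrt(var), g - 1
    else:
        se = float(errors.std(ddof=1) / math.sqrt(n))
        df = n - 1
    half = stats.t.ppf(0.5 + level / 2.0, df) * se
    return mean, (mean - half, mean + half)


def bias_regression(
    pairs: Sequence[MatchedPair],
    covariate_values: dict[str, float] | None = None,
    dataset: CohortDataset | None = None,
    covariate: Literal["weight", "creatinine", "duration"] = "weight",
) -> tuple[float, float, float]:
    """OLS of prediction error on a case covariate: (slope, se, p).

    Covariate values come either from an explicit ``case_id -> value`` map or
    from the dataset (weight kg, creatinine µmol/L, treatment duration h).
    """
    if covariate_values is None:
        if dataset is None:
            raise ValueError("provide covariate_values or dataset")
        covariate_values = {
            c.case_id: {
                "weight": c.weight,
                "creatinine": c.creatinine,
                "duration": c.duration,
            }[covariate]
            for c in dataset.cases
        }
    y = np.array([p.error for p in pairs], dtype=float)
    x = np.array([covariate_values[p.case_id] for p in pairs], dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 pairs for regression")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.bse[1]), float(model.pvalues[1])


def calibration_table(pairs: Sequence[MatchedPair], n_bins: int = 10) -> pd.DataFrame:
    """Mean measured concentration per equal-width bin of the predicted range.

    Columns: predicted_mid, mean_measured, count. Empty bins are omitted; a
    degenerate predicted range yields a single bin.
    """
    if not pairs:
        raise ValueError("no pairs to calibrate")
    pred = np.array([p.predicted for p in pairs], dtype=float)
    meas = np.array([p.measured for p in pairs], dtype=float)
    lo, hi = float(pred.min()), float(pred.max())
    if hi == lo:
        return pd.DataFrame(
            {"predicted_mid": [lo], "mean_measured": [float(meas.mean())], "count": [len(pairs)]}
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(pred, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "predicted_mid": float(0.5 * (edges[b] + edges[b + 1])),
                "mean_measured": float(meas[mask].mean()),
                "count": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def calibration_slope(pairs: Sequence[MatchedPair]) -> float:
    """OLS slope of measured on predicted (1 = perfect mean calibration)."""
    pred = np.array([p.predicted for p in pairs], dtype=float)
    meas = np.array([p.measured for p in pairs], dtype=float)
    model = sm.OLS(meas, sm.add_constant(pred)).fit()
    return float(model.params[1])


def period_summary(dataset: CohortDataset, pairs: Sequence[MatchedPair]) -> pd.DataFrame:
    """Per-period mean maintenance rate and measured concentration, with
    Welch comparisons between adjacent periods.

    The rate attributed to each observation is the maintenance rate in force
    at its sampling time. Columns: period, n, mean_rate_g_per_h,
    mean_measured_mmol_L, p_rate_vs_prev, p_conc_vs_prev (NaN for the first
    period or empty comparisons).
    """
    by_case = {c.case_id: c for c in dataset.cases}
    rates: dict[str, list[float]] = {lab: [] for lab in PERIOD_LABELS}
    concs: dict[str, list[float]] = {lab: [] for lab in PERIOD_LABELS}
    for p in pairs:
        case = by_case[p.case_id]
        rates[p.period].append(case.schedule.rate_at(p.time))
        concs[p.period].append(p.measured)

    rows = []
    for i, lab in enumerate(PERIOD_LABELS):
        row = {
            "period": lab,
            "n": len(concs[lab]),
            "mean_rate_g_per_h": float(np.mean(rates[lab])) if rates[lab] else np.nan,
            "mean_measured_mmol_L": float(np.mean(concs[lab])) if concs[lab] else np.nan,
            "p_rate_vs_prev": np.nan,
            "p_conc_vs_prev": np.nan,
        }
        if i > 0:
            prev = PERIOD_LABELS[i - 1]
            if len(rates[prev]) >= 2 and len(rates[lab]) >= 2:
                row["p_rate_vs_prev"] = float(
                    stats.ttest_ind(rates[prev], rates[lab], equal_var=False).pvalue
                )
            if len(concs[prev]) >= 2 and len(concs[lab]) >= 2:
                row["p_conc_vs_prev"] = float(
                    stats.ttest_ind(concs[prev], concs[lab], equal_var=False).pvalue
                )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AberrantRules:
    """Screening rule for spurious high readings: a spike above
    ``high_threshold`` followed within ``lookahead`` hours by a reading within
    ``rebound_tolerance`` of the last pre-spike level is flagged as aberrant.
    The last observation of a case is never auto-flagged (no follow-up), nor
    is a spike with no preceding reference level.
    """

    high_threshold: float = 3.5
    lookahead: float = 6.0
    rebound_tolerance: float = 0.5


def flag_aberrant(
    observations: Sequence[Observation],
    rules: AberrantRules | None = None,
) -> tuple[Observation, ...]:
    """Return the observations with aberrant flags set per the spike rule."""
    rules = rules or AberrantRules()
    obs = list(observations)
    flags = [o.aberrant for o in obs]
    for i, o in enumerate(obs):
        if o.conc <= rules.high_threshold or i == len(obs) - 1:
            continue
        # last preceding non-flagged reading is the pre-spike reference
        ref = next((obs[j].conc for j in range(i - 1, -1, -1) if not flags[j]), None)
        if ref is None:
            continue
        rebound = any(
            o2.time - o.time <= rules.lookahead and abs(o2.conc - ref) <= rules.rebound_tolerance
            for o2 in obs[i + 1 :]
        )
        if rebound:
            flags[i] = True
    return tuple(replace(o, aberrant=f) for o, f in zip(obs, flags))


def flag_cohort(dataset: CohortDataset, rules: AberrantRules | None = None) -> CohortDataset:
    """Apply the aberrant-spike rule to every case of a cohort."""
    return CohortDataset(
        cases=[c.with_observations(flag_aberrant(c.observations, rules)) for c in dataset.cases],
        rejected=list(dataset.rejected),
    )


def screen_toxicity(dataset: CohortDataset, threshold: float = 3.5) -> pd.DataFrame:
    """Review list of every measurement strictly above the toxicity threshold.

    ``resolved_by_resample`` is true when a later measurement of the same case
    is at or below the threshold. Columns: case_id, time_h, conc_mmol_L,
    resolved_by_resample.
    """
    rows = []
    for case in dataset.cases:
        for i, o in enumerate(case.observations):
            if o.conc > threshold:
                resolved = any(o2.conc <= threshold for o2 in case.observations[i + 1 :])
                rows.append(
                    {
                        "case_id": case.case_id,
                        "time_h": o.time,
                        "conc_mmol_L": o.conc,
                        "resolved_by_resample": resolved,
                    }
                )
    return pd.DataFrame(rows, columns=["case_id", "time_h", "conc_mmol_L", "resolved_by_resample"])
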