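"""Time-to-target analysis: Kaplan–Meier estimation and the log-rank test.

The "event" is the first *measured*, non-aberrant serum magnesium strictly
above the therapeutic target (default 2.0 mmol/L); cases that never show such
a measurement are right-censored at the earlier of their last observation and
the analysis horizon (default 25 h). Because events are defined on discrete
sampling times, the estimated time-to-target upper-bounds the true continuous
crossing time.

The product-limit estimator, the Greenwood variance (confidence interval on
the log-survival scale) and the k-group log-rank statistic are implemented
directly from their defining formulas.
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import ConcentrationProfile, time_to_threshold
from .io import CohortDataset

__all__ = [
    "EventRecord",
    "event_times",
    "KaplanMeierEstimate",
    "km_estimate",
    "success_at",
    "stratify_quartiles",
    "LogRankResult",
    "logrank_test",
]


@dataclass(frozen=True)
class EventRecord:
    """One case's event/censoring time for the target-concentration analysis."""

    case_id: str
    time: float
    event: bool
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError("event/censoring time must be > 0")


def event_times(
    dataset: CohortDataset,
    target: float = 2.0,
    horizon: float = 25.0,
    mode: Literal["measured", "predicted"] = "measured",
    profiles: dict[str, ConcentrationProfile] | None = None,
) -> list[EventRecord]:
    """Per-case time of first target exceedance, or censoring.

    ``measured`` (default): event at the first non-aberrant measurement
    strictly above target, censored at min(last observation, horizon).
    ``predicted``: event at the first predicted-grid crossing (requires
    profiles), censored at min(profile horizon, analysis horizon) — the
    protocol-simulation view of the same question.
    """
    records: list[EventRecord] = []
    for case in dataset.cases:
        if mode == "predicted":
            if profiles is None:
                raise ValueError("predicted mode requires profiles")
            prof = profiles[case.case_id]
            t = time_to_threshold(prof, target)
            if t is not None and 0 < t <= horizon:
                records.append(EventRecord(case.case_id, t, True))
            else:
                records.append(EventRecord(case.case_id, min(prof.horizon, horizon), False))
            continue
        clean = [o for o in case.observations if not o.aberrant]
        if not clean:
            continue
        hit = next((o.time for o in clean if o.conc > target), None)
        if hit is not None and hit <= horizon:
            records.append(EventRecord(case.case_id, hit, True))
        else:
            records.append(EventRecord(case.case_id, min(clean[-1].time, horizon), False))
    return records


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit estimate with Greenwood 95% CI (log-survival scale)."""

    event_times_: np.ndarray  # distinct event times, increasing
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        i = bisect_right(self.event_times_.tolist(), t)
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.event_times_,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def km_estimate(records: Sequence[EventRecord], level: float = 0.95) -> KaplanMeierEstimate:
    """Kaplan–Meier product-limit estimator.

    At each distinct event time t_i with n_i at risk and d_i events,
    S(t) = Π (1 − d_i/n_i); ties between events and censorings at the same
    time count the censored subjects as still at risk (events first). The CI
    is exp(log S ± z·se(log S)) with Greenwood's se²(log S) = Σ d/(n(n−d)),
    clipped to [0, 1].
    """
    if not records:
        raise ValueError("no event records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    distinct = np.unique(times[events])
    z = stats.norm.ppf(0.5 + level / 2.0)

    n_at_risk, n_events, surv, lo, hi = [], [], [], [], []
    s = 1.0
    greenwood = 0.0  # running Σ d/(n(n-d))
    for t in distinct:
        n = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        n_at_risk.append(n)
        n_events.append(d)
        s *= 1.0 - d / n
        if s > 0.0 and n > d:
            greenwood += d / (n * (n - d))
            se = math.sqrt(greenwood)
            lo.append(min(max(s * math.exp(-z * se), 0.0), 1.0))
            hi.append(min(max(s * math.exp(z * se), 0.0), 1.0))
        else:
            lo.append(0.0)
            hi.append(0.0 if s == 0.0 else 1.0)
        surv.append(s)
    return KaplanMeierEstimate(
        event_times_=distinct,
        at_risk=np.array(n_at_risk, dtype=int),
        events=np.array(n_events, dtype=int),
        survival=np.array(surv, dtype=float),
        ci_lower=np.array(lo, dtype=float),
        ci_upper=np.array(hi, dtype=float),
    )


def success_at(km: KaplanMeierEstimate, t: float) -> float:
    """Proportion of cases having reached target by time t: 1 − S(t)."""
    return 1.0 - km.survival_at(t)


def stratify_quartiles(
    dataset: CohortDataset,
    covariate: Literal["weight", "creatinine"],
) -> dict[str, list[str]]:
    """Partition case_ids into four near-equal groups by covariate rank.

    Q1 holds the lowest covariate values. Ties are broken by case_id order so
    the grouping is deterministic; group sizes differ by at most one. A
    constant covariate leaves quartiles undefined and raises ValueError.
    """
    values = [(getattr(c, covariate), c.case_id) for c in dataset.cases]
    if len(values) < 4:
        raise ValueError("need at least 4 cases to form quartiles")
    if len({v for v, _ in values}) == 1:
        raise ValueError(f"{covariate} is constant; quartiles undefined")
    ordered = [cid for _, cid in sorted(values)]
    n = len(ordered)
    base, extra = divmod(n, 4)
    groups: dict[str, list[str]] = {}
    start = 0
    for q in range(4):
        size = base + (1 if q < extra else 0)
        groups[f"Q{q + 1}"] = ordered[start : start + size]
        start += size
    return groups


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(groups: Sequence[Sequence[EventRecord]]) -> LogRankResult:
    """k-group log-rank test.

    At each distinct event time, the observed events per group are compared
    with their hypergeometric expectation given the group at-risk counts; the
    summed (O − E) vector over the first k−1 groups is referenced to
    chi-square with k−1 df through the summed hypergeometric covariance.
    """
    k = len(groups)
    if k < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    times = [np.array([r.time for r in g], dtype=float) for g in groups]
    events = [np.array([r.event for r in g], dtype=bool) for g in groups]
    all_event_times = np.unique(np.concatenate([t[e] for t, e in zip(times, events)]))

    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in all_event_times:
        n_g = np.array([np.sum(tt >= t) for tt in times], dtype=float)
        d_g = np.array([np.sum(ee & (tt == t)) for tt, ee in zip(times, events)], dtype=float)
        n, d = n_g.sum(), d_g.sum()
        if n <= 1 or d == 0:
            continue
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        c = d * (n - d) / (n - 1) / n**2
        cov += c * (n * np.diag(n_g) - np.outer(n_g, n_g))

    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    if np.allclose(u, 0.0) and np.allclose(v, 0.0):
        return LogRankResult(0.0, k - 1, 1.0)
    try:
        chi2 = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(v) @ u)
    chi2 = max(chi2, 0.0)
    return LogRankResult(chi2, k - 1, float(stats.chi2.sf(chi2, k - 1)))
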