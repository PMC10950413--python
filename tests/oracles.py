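"""Independent numerical oracles for the test suite.

These deliberately avoid the closed-form code paths they check: the
two-compartment system is integrated numerically with scipy's DOP853, with
the dosing history rendered as piecewise-constant input between breakpoints
(plus impulses for zero-duration boluses).
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from mgpk.dosing import DosingSchedule
from mgpk.params import PKParameters


def ode_concentrations(schedule: DosingSchedule, params: PKParameters, times) -> np.ndarray:
    """Total serum concentration by numerical ODE integration of

        dA1/dt = in(t) - (k10 + k12) A1 + k21 A2
        dA2/dt = k12 A1 - k21 A2,      C = baseline + A1/V1.
    """
    times = np.asarray(times, dtype=float)
    f = params.dose_to_amount
    deltas: dict[float, float] = {}
    impulses: dict[float, float] = {}
    for start, d in schedule.rate_deltas():
        deltas[start] = deltas.get(start, 0.0) + d * f
    for ev in schedule.boluses:
        if ev.bolus_duration > 0:
            r = ev.dose * f / ev.bolus_duration
            deltas[ev.time] = deltas.get(ev.time, 0.0) + r
            te = ev.time + ev.bolus_duration
            deltas[te] = deltas.get(te, 0.0) - r
        else:
            impulses[ev.time] = impulses.get(ev.time, 0.0) + ev.dose * f

    t_end = float(max([times.max(initial=0.0), *deltas.keys(), *impulses.keys(), 0.0]))
    bps = sorted({0.0, t_end} | set(deltas) | set(impulses))

    k10, k12, k21 = params.k10, params.k12, params.k21

    def rhs(t, y, rin):
        a1, a2 = y
        return (rin - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2)

    out = np.empty_like(times)
    y = np.zeros(2)
    rate = 0.0
    for i, b in enumerate(bps):
        if b in impulses:
            y[0] += impulses[b]
        rate += deltas.get(b, 0.0)
        out[times == b] = params.baseline + y[0] / params.V1
        if i + 1 == len(bps):
            break
        b2 = bps[i + 1]
        sol = solve_ivp(
            rhs, (b, b2), y, args=(rate,), method="DOP853",
            rtol=1e-11, atol=1e-13, dense_output=True,
        )
        assert sol.success, sol.message
        mask = (times > b) & (times < b2)
        if mask.any():
            out[mask] = params.baseline + sol.sol(times[mask])[0] / params.V1
        y = sol.y[:, -1]
    return out


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, se) of simple linear regression via (XᵀX)⁻¹Xᵀy."""
    X = np.column_stack([np.ones_like(x), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - 2)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    return float(beta[1]), float(se)
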