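"""Closed-form two-compartment engine vs. independent numerical oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mgpk.dosing import DosingEvent, DosingSchedule
from mgpk.engine import (
    DegenerateModelError,
    concentration_at,
    hybrid_constants,
    infusion_response,
    predict_profile,
    steady_state,
    time_to_threshold,
)
from mgpk.params import PKParameters

from conftest import random_params, random_schedule
from oracles import ode_concentrations


class TestHybridConstants:
    def test_unit_parameters_closed_form(self):
        p = PKParameters(CL=1, V1=1, Q=1, V2=1)
        alpha, beta = hybrid_constants(p)
        assert alpha == pytest.approx((3 + math.sqrt(5)) / 2, rel=1e-12)
        assert beta == pytest.approx((3 - math.sqrt(5)) / 2, rel=1e-12)
        assert alpha * beta == pytest.approx(1.0, rel=1e-12)

    def test_vieta_identities(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_params(rng)
            alpha, beta = hybrid_constants(p)
            assert alpha > beta > 0
            assert alpha * beta == pytest.approx(p.k10 * p.k21, rel=1e-12)
            assert alpha + beta == pytest.approx(p.k10 + p.k12 + p.k21, rel=1e-12)

    def test_roots_match_polynomial_oracle(self):
        p = PKParameters(CL=4, V1=20, Q=2, V2=30)
        alpha, beta = hybrid_constants(p)
        roots = np.roots([1.0, p.k10 + p.k12 + p.k21, p.k10 * p.k21])
        assert sorted([-alpha, -beta]) == pytest.approx(sorted(roots.real), abs=1e-10)

    def test_degenerate_q_zero(self):
        with pytest.raises(DegenerateModelError):
            hybrid_constants(PKParameters(CL=4, V1=20, Q=0, V2=30))


class TestInfusionResponse:
    def test_zero_rate_is_zero(self, params):
        t = np.linspace(0, 48, 20)
        assert np.all(infusion_response(0.0, t, params) == 0.0)

    def test_steady_state_limit(self, params):
        _, beta = hybrid_constants(params)
        rate = 4.06  # mmol/h
        assert infusion_response(rate, 200 / beta, params) == pytest.approx(
            rate / params.CL, rel=1e-9
        )

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            infusion_response(1.0, -0.1, params)

    def test_matches_ode_integration(self):
        rng = np.random.default_rng(11)
        times = np.array([0.5, 2.0, 10.0])
        for _ in range(5):
            p = random_params(rng)
            rate_gph = float(rng.uniform(0.2, 2.5))
            sch = DosingSchedule.from_events(
                [DosingEvent(0, "bolus", dose=0.0, bolus_duration=0.0),
                 DosingEvent(0, "rate_change", rate=rate_gph)],
                treatment_end=times[-1],
            )
            expected = ode_concentrations(sch, p, times) - p.baseline
            got = infusion_response(rate_gph * p.dose_to_amount, times, p)
            np.testing.assert_allclose(got, expected, atol=1e-6)


class TestPredictProfile:
    def test_zero_dose_constant_baseline(self, params):
        sch = DosingSchedule.from_events(
            [DosingEvent(0, "bolus", dose=0.0)], treatment_end=10.0
        )
        prof = predict_profile(sch, params, horizon=10.0)
        assert np.all(prof.conc == pytest.approx(0.74))

    def test_guideline_schedule_matches_ode(self, params, zuspan_schedule):
        prof = predict_profile(zuspan_schedule, params, horizon=30.0)
        expected = ode_concentrations(zuspan_schedule, params, prof.times)
        assert np.max(np.abs(prof.conc - expected)) < 1e-6

    def test_superposition_linearity(self, params):
        """Drug-attributable concentration is additive over dosing histories."""
        sch_a = DosingSchedule.from_events(
            [DosingEvent(0, "bolus", dose=4.0), DosingEvent(0, "rate_change", rate=1.0)],
            treatment_end=20.0,
        )
        sch_b = DosingSchedule.from_events(
            [DosingEvent(0, "bolus", dose=2.0), DosingEvent(3, "rate_change", rate=0.5)],
            treatment_end=20.0,
        )
        sch_ab = DosingSchedule.from_events(
            [
                DosingEvent(0, "bolus", dose=6.0),
                DosingEvent(0, "rate_change", rate=1.0),
                DosingEvent(3, "rate_change", rate=1.5),
            ],
            treatment_end=20.0,
        )
        t = np.linspace(0, 25, 301)
        a = concentration_at(sch_a, params, t) - params.baseline
        b = concentration_at(sch_b, params, t) - params.baseline
        ab = concentration_at(sch_ab, params, t) - params.baseline
        np.testing.assert_allclose(ab, a + b, atol=1e-9)

    def test_grid_is_uniform_and_starts_at_zero(self, params, zuspan_schedule):
        prof = predict_profile(zuspan_schedule, params, resolution=1 / 12, horizon=30.0)
        assert prof.times[0] == 0.0
        assert len(prof.times) == 361
        assert np.allclose(np.diff(prof.times), 1 / 12)

    def test_bolus_duration_limit_peak(self, params):
        """As bolus duration → 0, peak → baseline + dose·f/V1."""
        dose = 4.0
        expected = params.baseline + dose * params.dose_to_amount / params.V1
        for dur in (1e-3, 1e-5):
            sch = DosingSchedule.from_events(
                [DosingEvent(0, "bolus", dose=dose, bolus_duration=dur)], treatment_end=1.0
            )
            peak = concentration_at(sch, params, np.array([dur]))[0]
            assert peak == pytest.approx(expected, rel=5e-3 if dur > 1e-4 else 1e-4)
        sch0 = DosingSchedule.from_events(
            [DosingEvent(0, "bolus", dose=dose, bolus_duration=0.0)], treatment_end=1.0
        )
        assert concentration_at(sch0, params, np.array([0.0]))[0] == pytest.approx(expected)

    @given(scale=st.floats(0.25, 4.0))
    def test_monotone_in_dose_and_rate(self, scale):
        """Pointwise concentration is non-decreasing in bolus dose and rates."""
        p = PKParameters(CL=4, V1=20, Q=2, V2=30)
        base = DosingSchedule.from_events(
            [DosingEvent(0, "bolus", dose=4.0), DosingEvent(0, "rate_change", rate=1.0)],
            treatment_end=24.0,
        )
        bigger = DosingSchedule.from_events(
            [DosingEvent(0, "bolus", dose=4.0 * (1 + scale)),
             DosingEvent(0, "rate_change", rate=1.0 + scale)],
            treatment_end=24.0,
        )
        t = np.linspace(0, 30, 121)
        assert np.all(concentration_at(bigger, p, t) >= concentration_at(base, p, t) - 1e-12)

    def test_conc_never_below_baseline(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            p, sch = random_params(rng), random_schedule(rng)
            prof = predict_profile(sch, p, resolution=0.25, horizon=sch.treatment_end + 10)
            assert np.all(prof.conc >= p.baseline - 1e-12)


class TestSteadyState:
    def test_zero_rate_is_baseline(self, params):
        assert steady_state(0.0, params) == params.baseline

    def test_stated_formula(self):
        p = PKParameters(CL=4, V1=20, Q=2, V2=30, baseline=0.74, dose_to_amount=4.06)
        assert steady_state(1.0, p) == pytest.approx(1.755)

    def test_profile_converges_to_steady_state(self, params):
        _, beta = hybrid_constants(params)
        sch = DosingSchedule.from_events(
            [DosingEvent(0, "bolus", dose=0.0), DosingEvent(0, "rate_change", rate=1.0)],
            treatment_end=200 / beta,
        )
        prof = predict_profile(sch, params, resolution=5.0, horizon=200 / beta)
        assert prof.conc[-1] == pytest.approx(steady_state(1.0, params), rel=1e-6)


class TestTimeToThreshold:
    def test_threshold_below_baseline_is_zero(self, params, zuspan_schedule):
        prof = predict_profile(zuspan_schedule, params, horizon=30.0)
        assert time_to_threshold(prof, 0.5) == 0.0

    def test_threshold_above_max_is_none(self, params, zuspan_schedule):
        prof = predict_profile(zuspan_schedule, params, horizon=30.0)
        assert time_to_threshold(prof, prof.conc.max() + 0.1) is None

    def test_first_grid_point_strictly_above(self, params):
        """Crossing between grid points resolves to the first grid time above,
        consistent with a 100x denser grid."""
        sch = DosingSchedule.from_events(
            [DosingEvent(0, "bolus", dose=0.0), DosingEvent(0, "rate_change", rate=1.5)],
            treatment_end=120.0,
        )
        coarse = predict_profile(sch, params, resolution=0.5, horizon=120.0)
        fine = predict_profile(sch, params, resolution=0.005, horizon=120.0)
        t_coarse = time_to_threshold(coarse, 2.0)
        t_fine = time_to_threshold(fine, 2.0)
        assert t_fine <= t_coarse < t_fine + 0.5
        assert coarse.conc[int(t_coarse / 0.5)] > 2.0


def test_engine_oracle_equivalence_bulk():
    """Engine vs ODE integration on random parameter/schedule draws."""
    rng = np.random.default_rng(2024)
    worst = 0.0
    for _ in range(20):
        p, sch = random_params(rng), random_schedule(rng)
        t = np.linspace(0, sch.treatment_end + 5, 40)
        diff = np.abs(concentration_at(sch, p, t) - ode_concentrations(sch, p, t))
        worst = max(worst, float(diff.max()))
    assert worst < 1e-6
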