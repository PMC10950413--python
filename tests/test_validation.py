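"""Prediction-error statistics, calibration, period summaries, screening rules."""
import math

import numpy as np
import pytest
from scipy import stats

from mgpk.dosing import DosingEvent, DosingSchedule
from mgpk.engine import ConcentrationProfile, predict_profile
from mgpk.io import CaseRecord, CohortDataset, Observation
from mgpk.validation import (
    AberrantRules,
    MatchedPair,
    bias_regression,
    calibration_slope,
    calibration_table,
    flag_aberrant,
    match_predictions,
    mean_prediction_error,
    period_bin,
    period_summary,
    screen_toxicity,
)

from oracles import ols_normal_equations


def _pairs(errors, case_ids=None, times=None, predicted=2.0):
    case_ids = case_ids or [f"c{i}" for i in range(len(errors))]
    times = times if times is not None else [1.0 + i for i in range(len(errors))]
    return [
        MatchedPair(case_id=c, time=t, measured=predicted + e, predicted=predicted)
        for c, t, e in zip(case_ids, times, errors)
    ]


def _flat_profile(value=2.0, horizon=30.0, res=1 / 12):
    n = int(round(horizon / res))
    times = np.arange(n + 1) * res
    return ConcentrationProfile(times=times, conc=np.full(n + 1, value), resolution=res)


class TestMatching:
    def test_nearest_grid_point_within_half_resolution(self):
        prof = _flat_profile()
        pairs = match_predictions(prof, [Observation(1.02, 1.8)], "c1")
        assert len(pairs) == 1
        assert pairs[0].time == 1.02  # observation time kept
        # matched against grid node 1.0000 h
        assert prof.times[prof.nearest_index(1.02)] == pytest.approx(1.0)

    def test_aberrant_excluded_and_beyond_horizon_dropped(self):
        prof = _flat_profile(horizon=10.0)
        obs = [Observation(1.0, 1.8, aberrant=True), Observation(2.0, 1.9), Observation(25.0, 2.2)]
        pairs = match_predictions(prof, obs, "c1")
        assert [p.time for p in pairs] == [2.0]

    def test_empty_observations(self):
        assert match_predictions(_flat_profile(), [], "c1") == []


class TestMeanError:
    def test_perfect_predictions(self):
        mean, (lo, hi) = mean_prediction_error(_pairs([0.0, 0.0, 0.0]))
        assert mean == 0.0 and lo == 0.0 and hi == 0.0

    def test_hand_checked_t_interval(self):
        """errors {-0.2, 0, 0.2}: mean 0, half-width t(0.975,2)·0.2/√3 = 0.497."""
        mean, (lo, hi) = mean_prediction_error(_pairs([-0.2, 0.0, 0.2]))
        assert mean == pytest.approx(0.0, abs=1e-15)
        assert hi == pytest.approx(4.302653 * 0.2 / math.sqrt(3), abs=1e-4)
        assert lo == pytest.approx(-hi)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            mean_prediction_error(_pairs([0.1]))

    def test_clustered_interval_widens_under_case_correlation(self):
        # 10 cases x 5 pairs, strong within-case shifts
        rng = np.random.default_rng(0)
        pairs = []
        for c in range(10):
            shift = rng.normal(0, 0.3)
            for j in range(5):
                pairs.append(MatchedPair(f"c{c}", 1.0 + j, 2.0 + shift + rng.normal(0, 0.01), 2.0))
        _, (lo_p, hi_p) = mean_prediction_error(pairs)
        _, (lo_c, hi_c) = mean_prediction_error(pairs, cluster_by_case=True)
        assert (hi_c - lo_c) > (hi_p - lo_p)


class TestBiasRegression:
    def test_constant_error_zero_slope(self):
        pairs = _pairs([0.1] * 6)
        cov = {p.case_id: 60.0 + i for i, p in enumerate(pairs)}
        slope, se, p = bias_regression(pairs, covariate_values=cov)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_perfect_linear_bias(self):
        cov = {f"c{i}": float(i) for i in range(6)}
        pairs = _pairs([2.0 * i for i in range(6)])
        slope, se, p = bias_regression(pairs, covariate_values=cov)
        assert slope == pytest.approx(2.0, rel=1e-10)
        assert p < 1e-12

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(50, 110, 30)
        e = 0.01 * x + rng.normal(0, 0.1, 30)
        cov = {f"c{i}": float(v) for i, v in enumerate(x)}
        pairs = _pairs(list(e))
        slope, se, _ = bias_regression(pairs, covariate_values=cov)
        o_slope, o_se = ols_normal_equations(x, e)
        assert slope == pytest.approx(o_slope, abs=1e-10)
        assert se == pytest.approx(o_se, abs=1e-10)


class TestCalibration:
    def test_single_pair_single_bin(self):
        tab = calibration_table(_pairs([0.0], predicted=1.8), n_bins=5)
        assert len(tab) == 1 and tab["count"].iloc[0] == 1

    def test_perfectly_calibrated(self):
        rng = np.random.default_rng(2)
        pred = rng.uniform(1.0, 3.0, 2000)
        pairs = [MatchedPair(f"c{i}", 1.0, float(v), float(v)) for i, v in enumerate(pred)]
        tab = calibration_table(pairs, n_bins=8)
        np.testing.assert_allclose(tab["mean_measured"], tab["predicted_mid"], atol=0.15)

    def test_miscalibration_slope_recovered(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(1.0, 3.0, 500)
        pairs = [MatchedPair(f"c{i}", 1.0, 0.9 * float(v), float(v)) for i, v in enumerate(pred)]
        assert calibration_slope(pairs) == pytest.approx(0.9, abs=1e-9)


def _case_with_obs(cid, obs, weight=80.0, creat=60.0, end=30.0):
    sch = DosingSchedule.from_events(
        [DosingEvent(0, "bolus", dose=4.0), DosingEvent(0, "rate_change", rate=1.0),
         DosingEvent(4.0, "rate_change", rate=1.5)],
        treatment_end=end,
    )
    return CaseRecord(case_id=cid, weight=weight, creatinine=creat, schedule=sch,
                      observations=tuple(obs))


class TestPeriodSummary:
    def test_bin_edges(self):
        assert period_bin(3.9) == "early"
        assert period_bin(4.0) == "intermediate"
        assert period_bin(16.5) == "intermediate"
        assert period_bin(17.0) == "late"
        assert period_bin(25.0) == "extended"
        # partition of [0, 60]: every time gets exactly one label
        for t in np.linspace(0, 60, 1201):
            assert period_bin(float(t)) in ("early", "intermediate", "late", "extended")

    def test_rate_and_conc_means_with_welch(self):
        """Rates 1.0 in early vs 1.5 in intermediate: recovered means, Welch-significant."""
        rng = np.random.default_rng(4)
        cases, pairs = [], []
        for i in range(30):
            cid = f"c{i}"
            obs = [Observation(1.0, 1.5 + rng.normal(0, 0.05)),
                   Observation(8.0, 1.8 + rng.normal(0, 0.05))]
            cases.append(_case_with_obs(cid, obs))
            pairs += [MatchedPair(cid, o.time, o.conc, 1.7) for o in obs]
        ds = CohortDataset(cases=cases)
        tab = period_summary(ds, pairs).set_index("period")
        assert tab.loc["early", "mean_rate_g_per_h"] == pytest.approx(1.0)
        assert tab.loc["intermediate", "mean_rate_g_per_h"] == pytest.approx(1.5)
        assert tab.loc["intermediate", "p_conc_vs_prev"] < 1e-6
        # Welch formula hand-check on the concentration comparison
        a = np.array([p.measured for p in pairs if p.period == "early"])
        b = np.array([p.measured for p in pairs if p.period == "intermediate"])
        t_stat = (a.mean() - b.mean()) / math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(t_stat) > 5

    def test_empty_bins_reported(self):
        cases = [_case_with_obs("c0", [Observation(1.0, 1.5), Observation(2.0, 1.6)])]
        pairs = [MatchedPair("c0", 1.0, 1.5, 1.4), MatchedPair("c0", 2.0, 1.6, 1.5)]
        tab = period_summary(CohortDataset(cases=cases), pairs).set_index("period")
        assert tab.loc["early", "n"] == 2
        assert tab.loc["late", "n"] == 0 and np.isnan(tab.loc["late", "mean_measured_mmol_L"])


class TestScreening:
    def test_spike_with_rebound_flagged(self):
        obs = [Observation(1.0, 1.8), Observation(2.0, 7.28), Observation(3.0, 1.9)]
        out = flag_aberrant(obs)
        assert [o.aberrant for o in out] == [False, True, False]

    def test_monotone_series_not_flagged(self):
        obs = [Observation(1.0, 1.5), Observation(2.0, 1.8), Observation(3.0, 2.1)]
        assert not any(o.aberrant for o in flag_aberrant(obs))

    def test_final_exceedance_not_autoflagged(self):
        obs = [Observation(1.0, 1.8), Observation(2.0, 4.0)]
        out = flag_aberrant(obs)
        assert not any(o.aberrant for o in out)
        # but it is listed for manual review
        ds = CohortDataset(cases=[_case_with_obs("c0", obs)])
        review = screen_toxicity(ds)
        assert len(review) == 1 and not review["resolved_by_resample"].iloc[0]

    def test_rebound_outside_window_not_flagged(self):
        obs = [Observation(1.0, 1.8), Observation(2.0, 5.0), Observation(12.0, 1.9)]
        assert not any(o.aberrant for o in flag_aberrant(obs))

    def test_toxicity_review_resolved_by_resample(self):
        obs = [Observation(1.0, 1.8), Observation(2.0, 7.28), Observation(3.0, 1.9)]
        ds = CohortDataset(cases=[_case_with_obs("c0", obs)])
        review = screen_toxicity(ds)
        assert len(review) == 1
        assert bool(review["resolved_by_resample"].iloc[0])

    def test_clean_moderate_dose_cohort_empty_review(self):
        """No outlier injection + moderate dosing (1 g/h, no titration headroom):
        nothing approaches the 3.5 mmol/L reflex-loss threshold."""
        from mgpk.simulate import ErrorModel, ProtocolConfig, simulate_cohort

        ds = simulate_cohort(
            20, seed=6,
            protocol=ProtocolConfig(max_rate=1.0),
            error=ErrorModel(outlier_prob=0.0),
        )
        assert screen_toxicity(ds).empty
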