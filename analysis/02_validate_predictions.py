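"""External validation of the PK model on the simulated cohort.

Reads results/cohort/, predicts each case's concentration table from weight
and creatinine alone (5-min grid), time-matches the measurements, and
computes the prediction-error statistics, covariate bias regressions,
calibration table and treatment-period summary. Writes tables under
results/validation/.
"""
import json
import sys
from pathlib import Path

from mgpk.io import read_cohort
from mgpk.params import default_covariate_model, default_parameters
from mgpk.pipeline import predict_cohort
from mgpk import validation as val

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "results" / "cohort"
    ds = read_cohort(cohort_dir / "dosing.csv", cohort_dir / "observations.csv",
                     cohort_dir / "covariates.csv")
    print(f"ingested {len(ds.cases)} cases, {len(ds.rejected)} rejected")

    typical, covmodel = default_parameters(), default_covariate_model()
    profiles = predict_cohort(ds, typical, covmodel)
    ds = val.flag_cohort(ds)
    n_flagged = sum(o.aberrant for c in ds.cases for o in c.observations)
    pairs = val.match_cohort(ds, profiles)
    print(f"{len(pairs)} time-matched pairs ({n_flagged} aberrant readings excluded)")

    mean, ci = val.mean_prediction_error(pairs)
    _, ci_cl = val.mean_prediction_error(pairs, cluster_by_case=True)
    print(f"mean measured - predicted: {mean:+.3f} mmol/L "
          f"(95% CI {ci[0]:+.3f} to {ci[1]:+.3f}; case-clustered {ci_cl[0]:+.3f} to {ci_cl[1]:+.3f})")
    slopes = {}
    for cov in ("weight", "creatinine", "duration"):
        s, se, p = val.bias_regression(pairs, dataset=ds, covariate=cov)
        slopes[cov] = {"slope": s, "se": se, "p": p}
        print(f"  bias vs {cov:10s}: slope {s:+.5f} per unit (p = {p:.3f})")
    cal = val.calibration_slope(pairs)
    print(f"calibration slope (measured on predicted): {cal:.3f}")

    periods = val.period_summary(ds, pairs)
    print(periods.to_string(index=False))
    tox = val.screen_toxicity(ds)
    print(f"toxicity review (> 3.5 mmol/L): {len(tox)} reading(s), "
          f"{int(tox['resolved_by_resample'].sum()) if len(tox) else 0} resolved by resampling")

    out = ROOT / "results" / "validation"
    out.mkdir(parents=True, exist_ok=True)
    val.pairs_frame(pairs).to_csv(out / "pairs.csv", index=False, float_format="%.6g")
    val.calibration_table(pairs).to_csv(out / "calibration.csv", index=False, float_format="%.6g")
    periods.to_csv(out / "period_summary.csv", index=False, float_format="%.6g")
    tox.to_csv(out / "toxicity_review.csv", index=False, float_format="%.6g")
    (out / "error_summary.json").write_text(json.dumps({
        "n_pairs": len(pairs),
        "mean_prediction_error_mmol_L": mean,
        "ci95": list(ci),
        "ci95_case_clustered": list(ci_cl),
        "bias_slopes": slopes,
        "calibration_slope": cal,
    }, indent=2))
    print(f"wrote tables under {out.relative_to(ROOT)}/")


if __name__ == "__main__":
    sys.exit(main())
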