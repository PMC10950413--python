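"""Simulate the study cohort: 56 preeclampsia cases on the Zuspan protocol.

Draws demographics from the quartile-matched distributions, runs each case
through the titration closed loop (4 g bolus, 1 g/h maintenance, +0.25 g/h
when a 1-h check reads < 2 mmol/L, capped at 2 g/h), and writes the three
tidy CSVs under results/cohort/.
"""
import sys
from pathlib import Path

import numpy as np

from mgpk.io import weighted_mean_rate, write_cohort
from mgpk.simulate import simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
N = 56


def main() -> None:
    ds = simulate_cohort(N, seed=SEED)
    paths = write_cohort(ds, ROOT / "results" / "cohort")

    w = np.array([c.weight for c in ds.cases])
    cr = np.array([c.creatinine for c in ds.cases])
    dur = np.array([c.duration for c in ds.cases])
    rate = np.array([weighted_mean_rate(c.schedule) for c in ds.cases])
    n_obs = sum(len(c.observations) for c in ds.cases)

    print(f"simulated {len(ds.cases)} cases ({n_obs} magnesium measurements), seed {SEED}")
    print("cohort quartiles (Q1 / median / Q3):")
    for name, x in (("weight kg", w), ("creatinine umol/L", cr),
                    ("treatment duration h", dur), ("weighted mean rate g/h", rate)):
        q = np.percentile(x, [25, 50, 75])
        print(f"  {name:24s} {q[0]:6.1f} {q[1]:6.1f} {q[2]:6.1f}")
    print("wrote:", ", ".join(str(p.relative_to(ROOT)) for p in paths.values()))


if __name__ == "__main__":
    sys.exit(main())
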