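#!/usr/bin/env python
"""Adjusted population attributable fraction curves over follow-up.

For each factor, PAF(t) standardizes the cumulative-incidence of an
exceeding fill over the cohort's observed covariate paths and compares it
to the counterfactual in which the factor is set to its reference level:
the proportion of exceeding prescriptions that would be eliminated if
patients with the factor were treated like those without it.  Bootstrap
bands (patient resampling, full refit per replicate) are computed for the
strongest factor.
"""

from pathlib import Path

import pandas as pd

from ppi_overuse.config import RunConfig, SimulationConfig
from ppi_overuse.paf import default_grid, peak
from ppi_overuse.report import paf_with_bootstrap, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
FACTORS = ("inpatient", "nsaid", "anticoagulant", "aspirin")

cfg = RunConfig(seed=SEED, paf_factors=())
cfg.simulation = SimulationConfig(n_patients=2000, seed=SEED)
bundle = run_pipeline(cfg)
intervals = bundle["intervals"]
covs = bundle["meta"]["covariates"]
grid = default_grid(1095)

frames, peaks = [], []
for factor in FACTORS:
    n_boot = 30 if factor == "inpatient" else 0
    curve = paf_with_bootstrap(intervals, covs, factor, grid, n_boot=n_boot, seed=SEED)
    frames.append(curve.to_frame())
    t_pk, v_pk = peak(curve)
    peaks.append({"factor": factor, "peak_paf": round(v_pk, 3), "peak_day": t_pk})
    print(f"{factor:14s} peak PAF {v_pk:.3f} at day {t_pk:.0f}")

out = ROOT / "results"
out.mkdir(exist_ok=True)
pd.concat(frames, ignore_index=True).round(5).to_csv(out / "paf_curves.csv", index=False)
pd.DataFrame(peaks).to_csv(out / "paf_peaks.csv", index=False)

try:  # figure is a convenience; the CSV is the artifact
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for f in frames:
        ax.plot(f["t"], f["paf"], label=f["factor"].iloc[0])
    ax.set_xlabel("days since PUD diagnosis")
    ax.set_ylabel("adjusted population attributable fraction")
    ax.legend()
    fig.tight_layout()
    (ROOT / "scratch").mkdir(exist_ok=True)
    fig.savefig(ROOT / "scratch" / "paf_curves.png", dpi=150)
except Exception as exc:  # plotting must never fail the analysis
    print(f"(figure skipped: {exc})")

print("\nBaseline factors (inpatient) peak essentially at once and decay as "
      "both arms saturate; time-varying exposures (NSAID, anticoagulant, "
      "aspirin) rise first while exposure accumulates, then decay.")
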