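#!/usr/bin/env python
"""Fit the multivariable Andersen-Gill recurrent-event model.

Builds the counting-process data — per-patient (start, stop] intervals
split at exceeding-fill dates and time-varying co-medication changes,
censored at the earliest of a new PPI indication, the 3-year cap, the
regional deprescribing cutoff or the end of data — and fits the
proportional-intensity model by Cox partial likelihood with Breslow ties
and cluster-robust variance.  The factor/aHR/CI table mirrors the layout
of a multivariable association table.
"""

from pathlib import Path

from ppi_overuse.config import RunConfig, SimulationConfig
from ppi_overuse.report import run_pipeline

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

cfg = RunConfig(seed=SEED, paf_factors=())
cfg.simulation = SimulationConfig(n_patients=2000, seed=SEED)
bundle = run_pipeline(cfg)

fit = bundle["fit"]
tab = bundle["table2"]
truth = {
    "inpatient": 1.32, "black": 0.83, "female": 0.91,
    "prefrail": 1.06, "mildly_frail": 1.11, "moderately_frail": 1.15,
    "severely_frail": 1.08, "nsaid": 1.26, "aspirin": 1.15, "anticoagulant": 1.25,
}
tab = tab.assign(generative_ahr=tab["factor"].map(truth))

out = ROOT / "results"
out.mkdir(exist_ok=True)
tab.to_csv(out / "model_ahr.csv", index=False)
(ROOT / "scratch").mkdir(exist_ok=True)
bundle["intervals"].to_csv(ROOT / "scratch" / "counting_process.csv", index=False)

print(f"{fit.n_patients} patients, {fit.n_events} exceeding-fill events, "
      f"{len(bundle['intervals'])} risk intervals; converged in {fit.n_iter} "
      f"Newton steps (score sup-norm {fit.grad_norm:.1e})")
print(tab[["factor", "aHR", "ci_low", "ci_high", "generative_ahr"]]
      .round(3).to_string(index=False))
print("\nEvery generative hazard ratio lies inside its robust 95% CI "
      "in this replicate." if all(
          (tab["ci_low"] <= tab["generative_ahr"])
          & (tab["generative_ahr"] <= tab["ci_high"])
      ) else "\nSome generative values fall outside their CI in this single "
             "replicate (expected for ~5% of factors).")
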