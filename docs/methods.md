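# Methods

## The scientific question and the pipeline

Proton pump inhibitors (PPIs) are indicated for at most eight weeks when
treating acute peptic ulcer disease (PUD), yet prescriptions frequently
continue long past that. This package implements, end to end, the analysis
used to quantify that overuse and to identify the healthcare factors that
drive it in a new-user cohort of PUD patients:

1. **Cohort eligibility** (`cohort`): a patient enters at the first acute
   PUD diagnosis (index date) and must look like a true treatment
   initiator — an upper endoscopy in conjunction with the diagnosis, no
   prior chronic/unspecified PUD, no other indication for long-term PPI
   use, no PPI fill in the washout window, and a qualifying PPI fill
   within 14 days.
2. **Outcome classification** (`classify`): every PPI fill is classified
   against a 60-day approved-duration threshold (8 weeks rounded up to two
   30-day fills), with an exception for fills covering *H. pylori*
   eradication and — in a secondary analysis — for patients meeting any
   active gastroprotection guideline.
3. **Recurrent-event model** (`counting`, `agmodel`): fills exceeding the
   approved duration are recurrent outcomes; their association with
   patient factors is estimated with an Andersen–Gill
   multiplicative-intensity model on counting-process data with
   time-varying co-medication covariates and cluster-robust variance.
4. **Attributable fractions** (`paf`): the health-system impact of each
   factor is summarized as an adjusted time-to-event population
   attributable fraction curve with bootstrap bands.

Because the source data (an integrated health system's EHR/claims
warehouse) is not public, the package ships a first-class synthetic cohort
generator (`simulate`) with the statistical structure the analysis
assumes; every stage is exercised and validated on it.

## The model

For patient *i* with covariate path $Z_i(t)$ (baseline indicators plus
time-varying medication-exposure indicators), exceeding-fill events arrive
with intensity

$$\lambda_i(t) = \lambda_0(t)\, e^{\beta^\top Z_i(t)},$$

*t* measured in days since index. $\beta$ is estimated by the Cox partial
likelihood over the counting-process risk sets $\{i: \text{start}_i < t
\le \text{stop}_i\}$, with **Breslow** handling of tied (integer-day)
event times — the standard choice for counting-process recurrent data.
Optimisation is Newton–Raphson with step-halving on internally
standardized covariates; convergence requires a standardized score
sup-norm below 1e-8 or a relative log-likelihood change below 1e-10, and
every fit asserts a final score sup-norm below 1e-6. Risk-set sums are
computed in $O(R\log R)$ per iteration via sorted suffix cumulative sums
over interval starts and stops.

Within-patient event dependence is handled with the **cluster-robust
sandwich**: score residuals are aggregated per patient before forming the
middle matrix, exactly as `survival::coxph(..., cluster(id))` does (the
two agree to 1e-10 on a shared fixture; the naive inverse-information
covariance is retained for diagnostics only). Reported 95% CIs are
$\exp(\hat\beta \pm 1.96\,\widehat{se}_{robust})$.

The **Breslow baseline** $\hat\Lambda_0(t)=\sum_{t_j\le t} d_j / \sum_{R(t_j)}
e^{\hat\beta^\top Z_i}$ feeds the PAF standardization.

A backward-elimination helper (`parsimonious_select`, drop the largest
robust Wald p-value above 0.05 per step) mirrors parsimonious model
building; it is optional and off by default since the full model is the
validated surface.

## Adjusted PAF over time

For factor $k$,

$$\mathrm{PAF}(t) = 1 - \frac{\bar F_0(t)}{\bar F(t)}, \qquad
\bar F(t) = \frac1n \sum_i g\!\big(\hat\Lambda_i(t)\big),$$

where $\hat\Lambda_i(t)$ accumulates $e^{\hat\beta^\top Z_i(s)}
d\hat\Lambda_0(s)$ piecewise along patient *i*'s observed covariate path
(held at the last observed values past the end of follow-up), and $\bar
F_0$ repeats the computation with factor $k$ set to its reference level
everywhere. Two estimator variants are declared because the estimator
behind the published curves is not fully specified:

* `cumulative_incidence` (default): $g(x)=1-e^{-x}$, the probability of at
  least one exceeding fill by *t*. Near $t=0$ this tends to the classical
  $p(r-1)/(1+p(r-1))$ limit; it returns to 0 as both arms saturate.
* `expected_events`: $g(x)=x$, the mean cumulative count; constant in *t*
  for purely baseline covariates.

Under both variants, an 18%-prevalence factor with aHR 1.32 has a peak PAF
near 0.05 — the magnitudes of the published peak fractions (≈0.26) are not
reachable from the published hazard ratios under either variant, so PAF
correctness is validated against the closed-form exponential oracle
(agreement to 1e-6 with exact inputs) rather than against printed peak
values. Grid points where $\bar F(t)=0$ are reported as missing, not zero.
Uncertainty bands resample patients with replacement, refit the model and
recompute the curve per replicate (percentile 2.5/97.5; failed replicates
dropped and counted, warning above 5%).

## The synthetic cohort generator

The generator emulates exactly the structure the estimator assumes, so
parameter-recovery studies are a clean test of the statistics:

* **Baseline factors** drawn independently at the source cohort's
  marginals: inpatient diagnosis 18%, Black race 18%, female 7%, frailty
  levels 24/43/22/8/3% (nonfrail…severely frail). Any extra key in
  `factor_prevalences` becomes a 0/1 column, which is how calibration
  studies add a pure-noise covariate.
* **Generative effects** default to the multivariable aHRs the analysis is
  built to estimate: inpatient 1.32, NSAID 1.26, anticoagulant 1.25,
  aspirin 1.15, Black race 0.83, female 0.91, frailty 1.06/1.11/1.15/1.08.
  Near-null continuous effects (age, calendar year, concurrent
  prescriptions) are omitted from the generative intensity by default.
* **PPI fills** arrive by thinning from the multiplicative intensity over
  `(0, horizon]`; the qualifying initial fill lands uniformly in
  `[index, index+14]`. Fill times are recorded as `ceil(t)` days, which
  makes integer event days exactly consistent with the half-open exposure
  windows at both edges. The baseline intensity default (0.0009/day ≈
  0.33/person-year) was chosen so the mean number of exceeding fills per
  cohort patient over three years (≈1.05) matches the source cohort's
  aggregate burden.
* **Co-medication episodes** (NSAID, aspirin, anticoagulant, antiplatelet,
  H2RA) arrive as Poisson processes (onsets up to 180 days *before* index,
  so exposure can be active at diagnosis) and are dispensed as successive
  30-day fills covering the episode; analgesic courses default to 60 days,
  antithrombotic therapy to 180. The exposure indicator entering the
  generative intensity is the same operational rule the analysis
  reconstructs — days covered by supply plus a 30-day grace window — so
  generation and ascertainment cannot drift apart.
* **Censoring/qualifying events**: exponential times to a new long-term
  PPI indication (default 0.04/year) and to a GI bleed (0.02/year, which
  can qualify a patient under the 2010 bleeding-history guideline); 20% of
  patients get a positive *H. pylori* test within two weeks of index.
* Identical seeds give bit-identical tables; `ineligible_fractions` can
  flag patient subsets violating one eligibility rule each (all zero by
  default) so attrition flowcharts have content.

**What passing tests do and do not show.** The generator has no unobserved
patient frailty term (deliberately: the fitted model has none either, and
frailty terms are out of scope), so it cannot jointly reproduce the real
cohort's 35% any-exceed proportion *and* median of 3 exceeding fills among
those patients — marginals that imply strong between-patient
overdispersion. Matching the mean burden makes the simulated any-exceed
proportion higher (≈65–78%) and the median count lower than the real
cohort's. Parameter recovery on these cohorts therefore validates the
estimation machinery under correct specification; it does not demonstrate
robustness to the unmeasured heterogeneity real data surely contains
(the cluster-robust variance is the standard guard there). Calendar
structure (diagnosis years 2000–2019, guideline activation years, a
regional deprescribing cutoff in one network) is simulated; coding
vocabularies, provider networks and administrative detail are not.

## Dates, calendars and rule activation

All dates are integer day offsets from a configurable study start
(1999-01-01); calendar years derive from it. Gastroprotection guidelines
activate on January 1 *after* their introduction year: PUD-history+NSAID
(2009→2010), GI-bleed history (2010→2011), antiplatelet plus one of
age>65/anticoagulant/NSAID/aspirin (2010→2011), aspirin+antiplatelet
(2017→2018), aspirin+anticoagulant (2018→2019), any two of
aspirin/NSAID/anticoagulant/antiplatelet (2020→2021). Activation years are
config-overridable. Qualification timing is found exactly by evaluating
the piecewise-constant patient state at its breakpoints (medication window
edges, bleed dates, activation days, the day the patient turns 66).

## Numerical and convention decisions

* 60-day threshold: strict (`supply_end > index+60` exceeds; exactly 60 is
  approved). *H. pylori* margin: inclusive (`supply_end ≤ hp+60` approved;
  only the first diagnosis counts). Washout `[index−365, index−14]` closed
  on both ends; initiation window `[index, index+14]` inclusive;
  endoscopy "in conjunction" window ±30 days (configurable).
* Backstock is ignored by construction: each fill is classified on its own
  dates.
* Event time is the **fill date** of the exceeding prescription (not the
  day its supply crosses the threshold) — the outcome is the prescribing
  decision.
* Risk intervals are half-open `(start, stop]`; events sit at interval
  stops; several exceeding fills on one day collapse to one event; an
  event exactly at the censor time is kept; a same-day covariate change
  and event leaves the pre-change value in force (the change applies from
  the next interval). Events dated on day 0 (possible only for a >60-day
  supply dispensed on the index day) cannot be represented in `(0, ·]`
  rows and are dropped with a log message.
* Censoring is the earliest of: first post-index disqualifying diagnosis
  (new PPI indication or chronic/unspecified PUD code), the follow-up cap
  (1095 days; 1825 in the sensitivity variant), the regional cutoff
  (2013-08-01) for patients in network 17, end of data (2022-12-31) and —
  secondary analysis only — first guideline qualification. Ties resolve by
  that priority order, administrative causes last. Death is not modelled
  separately; end of data acts as administrative censoring.
* "Days of excess PPI exposure" defaults to the summed days supply of
  exceeding fills; a `covered_after_60` alternative (union of supply days
  past index+60) is a config flag.
* The frailty-recomputation sensitivity uses a precomputed alternative
  frailty column in the patients table (the frailty-index internals are
  out of scope).

## Problem sizes

Defaults were chosen as the smallest sizes at which the statistical
questions are answerable with comfortable margins: recovery studies use 20
replicates of n=2000 over a 3-year horizon (≈2300 events per replicate;
Monte-Carlo SE of a mean aHR ≈0.02), null calibration uses 200 replicates
of n=1000, the cross-implementation fixture has 200 patients, and analysis
drivers run single n=1200–2000 cohorts. One replicate of the full pipeline
at n=2000 runs in about a second.

## Known limitations

* No frailty/random-effect or gap-time/PWP variants (out of scope).
* The PAF estimator variants are declared assumptions, not a
  reconstruction of the unpublished reference estimator; bootstrap bands
  quantify sampling noise only.
* The medication-ascertainment rule (supply + 30-day grace) is an
  operational assumption; the source's exact procedure is unpublished.
* Continuous-time intensities are discretized to integer days at
  recording; effects are negligible at the configured intensities but
  would matter for intensities approaching 1/day.
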