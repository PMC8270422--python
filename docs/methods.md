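# Methods

## Model structure

The package implements a patient-level discrete-time outcomes model for
prediabetes and type 2 diabetes. A simulated individual carries
demographics (age, sex, smoking), glycemic status and diabetes duration,
ten biomarkers (HbA1c %, SBP/DBP mmHg, HDL/LDL/triglycerides mmol/L, BMI
kg/m², eGFR mL/min/1.73 m², hemoglobin g/L, WBC ×10⁹/L), four medication
flags (insulin, oral hypoglycemic agents, antihypertensives, statins) and
thirteen history-of-event flags. Cycles are annual; the survival time axis
is **time since enrollment**, so an equation's S(t) is conditional on the
individual's covariates as of the current cycle.

### Risk equations

Each of the 13 outcomes has one accelerated-failure-time equation fitted
on the pooled prediabetes+diabetes population with glycemic status (and
duration) as covariates; progression to diabetes applies to the
prediabetes subgroup only. The AFT parameterisation was chosen because
effect sizes are reported as survival time ratios; for the Weibull and
exponential families this is an exact reparameterisation of the
proportional-hazards form, and for log-logistic/log-normal AFT is the only
coherent reading. Continuous predictors may take a restricted cubic spline
with 3 knots at the 10/50/90 percentiles of the development data
(type-7/linear-interpolation percentiles — stated because knot values
shift with the rule), using the (k₃−k₁)² basis normalisation so the
nonlinear term is zero below the first knot and linear beyond the last.

### Discrete-time embedding

The continuous survival curve is converted to an annual probability
conditional on survival to the cycle start, with covariates frozen within
the cycle:

    p_u = 1 − S(u+1 | η)/S(u | η).

The product of per-cycle survivals therefore reproduces S(T) exactly under
constant covariates (verified to 1e−12 in the tests). S(u) underflowing to
zero returns p = 1 with a warning.

### Cycle mechanics

Within a cycle, uniforms are drawn for **all** outcomes in a fixed order —
mortality first, the remaining outcomes alphabetically — and draws are
independent; death does not block same-cycle draws, so times to other
events in a death cycle are still recorded. Outcomes with a history flag
are absorbing: after the first event they become covariate history and are
not re-drawn (the risk equations model first events). Events are dated at
the end of the cycle (time u+1) with no half-cycle correction. Survivors
get age+1, enrollment-clock+1, duration+1 if diabetic; a prediabetes
individual who converts ends the cycle as diabetic with duration 0.
Biomarkers advance at cycle end for use in the next cycle's equations.
Medications are held at baseline unless a scenario overrides them; eGFR,
hemoglobin and WBC are risk-equation covariates but are not progressed
(held at baseline) — a recorded limitation.

Randomness is counter-based: each (replicate, cycle) pair keys its own
Philox stream and the uniform matrix is indexed by (individual row,
outcome), so results are independent of iteration order and bit-exact
under a fixed seed.

### Biomarker trajectories

Each progressed biomarker follows an OLS model of the current annual
average on its lag-1 and lag-2 annual averages, age, sex (female = 1),
duration, and medication flags; fit quality is the residual RMSE, which
also scales the optional stochastic innovation during simulation. In the
first simulation cycles the lag-2 (and lag-1) averages do not exist; both
are cold-started at the baseline value, which is unbiased under the
fitted stationary dynamics. Predictions are floored at a small positivity
epsilon (10⁻³) per biomarker.

## Estimation

`build_person_periods` averages within-year duplicate measurements (that
averaging *is* the annual smoothing), carries covariates forward over gap
years with a `carried_forward` flag, recomputes history flags from
baseline flags plus prior events (monotone by construction; an event in
cycle u is history from cycle u+1), truncates rows after death, and forms
per-outcome risk sets (alive; not yet in history; prediabetes only for
diabetes onset).

`fit_aft` maximises the right-censored episode likelihood: an episode
(a, b] with covariates x contributes S(b|x)/S(a|x) if event-free and
f(b|x)/S(a|x) if the event occurred at b — the standard counting-process
decomposition for time-varying covariates. Because panels generated by
annual Bernoulli draws are interval-censored within the year, the matched
alternative `event_likelihood="interval"` (contribution
(S(a)−S(b))/S(a)) is provided and used when refitting simulator-generated
data. Columns are standardised internally for optimiser conditioning
(L-BFGS-B, relative tolerance 1e−8, 200 iterations; a tiny gradient at
termination counts as converged); standard errors come from the numerical
Hessian by the delta method. |standardised β| > 50 is reported as
separation, naming the covariate.

AIC = 2k − 2ℓ governs both family selection (ties broken towards the
simpler family in the order exponential < Weibull < log-logistic <
log-normal) and optional backwards elimination, in which a spline's
linear+nonlinear pair drops as a unit while the nonlinear part may drop
alone. Backwards selection is a flag, off by default, because variable
vetting in practice also involves clinical judgement that a program cannot
supply.

Parameter uncertainty is by bootstrap over individuals (all of a person's
episodes move together; non-converged replicates are dropped and
counted). Overfitting-corrected Harrell's C and Brier at a fixed horizon
use the Harrell optimism procedure: corrected = apparent − mean over
replicates of (performance on the bootstrap sample − performance of the
bootstrap model on the original data).

## Validation metrics

Harrell's C counts a pair as usable iff the strictly shorter follow-up
time is an event; tied risk scores earn half credit; tied times are not
compared. The implementation is checked against an O(n²) pair-enumeration
oracle and against an independent survival-analysis library on tie-free
data. CIs are percentile bootstrap over individuals (default B = 100).

Calibration starts from deciles of predicted risk and coarsens one group
at a time (floor 3) until every group holds ≥ 5 observed events, then
regresses observed proportion on mean predicted risk (ideal slope 1,
intercept 0). Observed 10-year status uses event-by-horizon among those
with ≥ horizon follow-up or an earlier event; individuals censored early
without an event are excluded from Brier (an inverse-probability-weighted
variant is a noted alternative, not the default). RMSPE is
√mean((pred−obs)²) with both sides in percentage points; a `relative`
mode divides by the observed value first. R² is computed about the
identity line of the predicted-versus-observed scatter, not a refitted
line, matching how endpoint scatterplots are read.

## Trial-arm cohorts

A trial arm is reconstituted from its published table: continuous
baselines are truncated-normal (scipy's exact sampler; bounds from
protocol inclusion criteria; an error if the bounds exclude > 99.9 % of
the mass), binary characteristics are Bernoulli at the reported
prevalence, and covariates are sampled independently (marginals only — a
recorded simplification). Covariates the trial did not report must be
given explicit `fill` values in the YAML spec; a covariate the model needs
that is neither sampled nor filled is an error listing the gaps. Treatment
effects are fractions of the baseline mean (e.g. an absolute HbA1c change
of 0.05 on a baseline mean of 5.9 is 0.85 %); the full effect is reached
in year 2 and holds the biomarker at its year-1 value × (1 − fraction)
thereafter — a step, not a ramp. Endpoint convergence is monitored by the
running cumulative-incidence mean versus participants simulated; at
100,000 participants the final-50,000 drift is below 0.2 percentage
points.

## Synthetic development cohort

The generator emulates a registry-like longitudinal cohort: baseline
distributions per glycemic group are anchored to a published baseline
table of a large Chinese prediabetes/diabetes registry (43.5 % diabetes;
e.g. HbA1c 7.8 ± 1.7 for diabetes, 5.9 ± 0.3 for prediabetes; age 63.4 ±
12.8 / 60.0 ± 12.6), with physiological rather than diagnostic truncation
bounds so the published moments are preserved (treated diabetes commonly
sits below the 6.5 % cut). Diabetes duration at baseline is a point mass
at 0 (probability 0.5) plus a capped exponential tail (scale 3 years, cap
12) consistent with a median of 0. True risk-equation intercepts are
calibrated so that 10-year survival at the cohort covariate means matches
target crude rates, with mortality anchored at 0.025 deaths/person-year;
the other outcomes use plausible registry magnitudes (0.001–0.015/year;
diabetes onset 0.06/year among prediabetes). Events are drawn cycle by
cycle from the true equations, biomarkers evolve by the true trajectory
equations with Gaussian noise, and administrative censoring draws a
uniform 1–12-year follow-up, mimicking staggered accrual over a 12-year
window. Every parameter and seed lands in a manifest.

What the generator does **not** emulate: measurement missingness beyond
complete records, visit irregularity, correlated baseline covariates,
medication changes over time, and coding noise in event ascertainment.
Passing tests therefore demonstrate internal correctness of estimation and
simulation under the model's own assumptions, not robustness to real
registry artefacts.

## Self-consistency checks and problem sizes

Two checks deserve explanation. **Parameter recovery** draws continuous
AFT event times (n = 20,000 per family, ~30 % uniform censoring) split
into yearly episodes with a fractional final episode, so the continuous
episode likelihood is exactly matched; every coefficient must fall within
3 standard errors and AIC must identify the generating family (Weibull
with σ̂ ≈ 1 is accepted for exponential data, which it nests exactly).
**Self-consistency calibration** simulates 50,000 individuals under a
constant-covariate bundle — identity zero-noise biomarker progression, no
age/duration/history terms, baseline histories zeroed — because only then
is the baseline-covariate prediction 1 − S(10|η) the exact law of the
simulated times; slope and intercept are computed pooling 4 Monte Carlo
replicates so that binomial noise sits well inside the ±0.01 intercept
band. With evolving covariates the same comparison is *expected* to drift
from identity (ageing raises late-cycle hazards above the
baseline-covariate prediction), which is a property of time-varying
models, not a bug. Endpoint RMSPE is checked on five non-fatal outcomes
with mortality switched off so death does not compete.

Other sizes: the constant-hazard closed form (annual p = 0.1, ten years,
against 1 − 0.9¹⁰) uses 100,000 individuals; the concordance oracle runs
100 random instances of n ≤ 200; trial-arm checks use 100,000
participants. These sizes keep Monte Carlo error a few multiples below
each tolerance while the whole battery completes in well under a minute.

## Known limitations

- eGFR, hemoglobin and WBC do not progress; renal-function feedback on
  risk is therefore static.
- Competing events within a cycle are drawn independently; no event
  ordering beyond the fixed draw order, and no recurrent events.
- Trial-arm covariates are sampled marginally; correlations (e.g.
  age–SBP) are ignored.
- The discrete annual clock dates all events at cycle ends; outcomes with
  strong within-year dynamics are coarsened.
- Family selection on annually-discretised panels is less sharp than on
  continuous times; closely related families (e.g. Weibull vs log-normal
  at similar shapes) can swap under discretisation.
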