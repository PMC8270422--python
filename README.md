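# chime-model

An individual-level, discrete-time outcomes model for **prediabetes and
type 2 diabetes**, aimed at epidemiologists and health-economic modellers
who need lifetime projections of diabetes complications — particularly for
East Asian populations, where models built on historical European cohorts
calibrate poorly.

The model couples three pieces:

1. **Thirteen risk equations** — parametric accelerated-failure-time (AFT)
   survival models for all-cause mortality, myocardial infarction, ischemic
   heart disease, heart failure, cerebrovascular disease, peripheral
   vascular disease, neuropathy, amputation, skin ulcer, renal failure,
   cataract, retinopathy, and (for prediabetes) progression to diabetes.
   With linear predictor η = β₀ + Σβⱼxⱼ on the log-time scale, the four
   supported families are

   | family | S(t) |
   |---|---|
   | Weibull | exp(−(t/e^η)^{1/σ}) |
   | exponential | Weibull with σ = 1 |
   | log-logistic | 1 / (1 + (t/e^η)^{1/σ}) |
   | log-normal | 1 − Φ((ln t − η)/σ) |

   so exp(βⱼ) is a **survival time ratio** (> 1 protective). Continuous
   predictors may enter through restricted cubic splines with three knots
   at the 10th/50th/90th percentiles.

2. **Seven biomarker trajectory equations** — OLS models that advance
   HbA1c, systolic/diastolic blood pressure, HDL, LDL, triglycerides and
   BMI each year from their lagged annual averages in the previous two
   years plus age, sex, diabetes duration and medications.

3. **An annual-cycle microsimulation**: each cycle converts every
   applicable equation into a conditional annual event probability
   p_u = 1 − S(u+1)/S(u), draws events, updates age, histories, glycemic
   status and biomarkers, and repeats to the horizon. Trial arms can be
   reconstituted from published aggregate baselines (truncated-normal /
   Bernoulli sampling) with biomarker treatment effects phased in at
   year 2.

The estimation side fits all equations from a person-period panel
(censored maximum likelihood with time-varying covariates, AIC family
selection, optional AIC backwards elimination, bootstrap parameter
uncertainty, optimism-corrected Harrell's C), and a validation battery
provides Harrell's C with bootstrap CIs, Brier score, calibration
slope/intercept by risk deciles with a small-count regrouping rule, RMSPE
and R².

## Worked example

Generate a synthetic development cohort with known ground truth, fit the
full model, and simulate ten years:

```sh
chime synth --n 2000 --seed 11 --follow-up 6 --out data
chime fit --panel data/panel.csv --config fitspec.yaml --out model.json
chime simulate --cohort data/baseline.csv --model model.json \
    --horizon 10 --seed 7 --out sim
```

with `fitspec.yaml`:

```yaml
default:
  terms: [age, female, diabetes, hba1c, sbp]
  spline: [hba1c]
```

`chime fit` logs one line per outcome, e.g.

```
mortality: family=lognormal AIC=2318.9 events=265
ihd: family=lognormal AIC=1348.5 events=134
diabetes_onset: family=lognormal AIC=2204.5 events=317
```

(the selected family, its AIC, and the number of events it was fitted on),
and `sim/summary.json` holds the cohort's cumulative incidence per outcome.
For this run:

```
mortality         30.3 %
ihd               15.2 %
cerebrovascular   13.9 %
renal_failure     10.7 %
cataract          17.8 %
diabetes_onset    26.9 %
```

i.e. 30.3 % of the cohort died within ten years and 26.9 % of the
prediabetes subgroup progressed to diabetes. The same functionality is
available as a library (`chime.simulate_cohort`, `chime.fit_aft`,
`chime.generate_arm`, …); `chime trial` and `chime validate` cover
trial-arm simulation and multi-model validation reports.

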