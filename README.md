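# iopw

Two-step propensity weighting for estimating a treatment effect in one
patient cohort and *transporting* it to another.

`iopw` is aimed at biostatisticians and epidemiologists analysing
observational time-to-event data — for example, comparative effectiveness of
two cancer therapies in an EHR-derived cohort — when the clinically relevant
question concerns a *different* population than the one in which treatment
contrasts can be observed. The package implements:

1. **Step 1 — confounding adjustment (IPTW).** In the "original" cohort
   (membership indicator *S* = 1), a logistic regression of the binary
   treatment *A* on confounders *C* gives the propensity
   *Pᵢ = P(Aᵢ = 1 | Cᵢ)*, and each patient receives the stabilized inverse
   probability of treatment weight

   *Wᵢ = Aᵢ · P(A=1)/Pᵢ + (1 − Aᵢ) · P(A=0)/(1 − Pᵢ).*

2. **Step 2 — transport (IOPW).** Effect modifiers *E* are observed in both
   the original cohort and a disjointly defined "target" cohort (*S* = 0).
   A logistic regression of *S* on *E* over the combined rows gives the
   participation score *Qᵢ = P(Sᵢ = 1 | Eᵢ)*, and the composed inverse odds
   of participation weight

   *Vᵢ = Wᵢ · (1 − Qᵢ)/Qᵢ · P(S=1)/P(S=0)* for original rows, *Vᵢ = 0* for
   target rows,

   so that the V-weighted original cohort matches the target cohort's
   effect-modifier distribution.

Hazard ratios come from a weighted, treatment-only Cox model with a robust
(sandwich) variance; the proportional-hazards assumption is checked with
Schoenfeld residuals. Balance is diagnosed with standardized mean
differences (SMD, flagged above 0.1; continuous, binary and multinomial
Mahalanobis variants), and cohort similarity with the **Tipton index** — the
Bhattacharyya coefficient ∫√(f₁(p)f₂(p))dp of the two cohorts'
participation-score densities, a [0, 1] similarity where values above 0.8
support credible reweighting. Missing covariates are handled by
chained-equations multiple imputation (impute first, derive scores within
each completed dataset) and the per-imputation log hazard ratios are pooled
with Rubin's rules. A synthetic-cohort generator with known ground truth
(including a counterfactual Monte-Carlo oracle for the marginal hazard
ratio in either population) makes every stage testable.

## Worked example

```python
from iopw import TwoStepWeightedCox, generate_cohorts, impose_missingness, table_like_config

# a synthetic pair of cohorts emulating a two-line oncology registry:
# 752 second-line patients with treatment + outcome, 3,109 first-line
# patients with covariates only, ~29% missing performance status
config = table_like_config(n_original=752, n_target=3109, seed=7)
cohort, truth = generate_cohorts(config)
cohort = impose_missingness(cohort, config)

model = TwoStepWeightedCox(cohort, config.covariate_kinds(), m=5)
results = model.fit(seed=7)
print(results.summary())
```

```
Two-step weighted Cox analysis
==================================
Step 1 (IPTW, confounding): HR 1.34 [1.14, 1.58]  m=5
  events (median across imputations): 637
  PH test p median (min, max): 0.5303 (0.4627, 0.6127)
  max weighted SMD (median across imputations): 0.018 (all below 0.1)
Step 2 (IOPW, transport):   HR 1.29 [1.06, 1.59]  m=5
  Tipton index mean (SD): 0.95 (0.00)
  PH test p median (min, max): 0.3415 (0.2987, 0.4236)
  max weighted SMD (median across imputations): 0.088 (all below 0.1)
```

Reading the output: the step-1 line is the confounding-adjusted hazard ratio
of treatment in the original cohort with its Rubin-pooled 95% CI over m = 5
imputations; every confounder SMD after weighting sits below the 0.1
convention, and large Schoenfeld p-values give no evidence against
proportional hazards. The step-2 line transports that estimate to the
target population: the Tipton index of 0.95 says the two cohorts'
participation-score distributions overlap strongly (little extrapolation),
and the V-weighted modifier SMDs are likewise below 0.1. Here the two
hazard ratios are similar, indicating modest effect modification across the
covariates that differ between cohorts.

Each stage is also available on its own (`fit_treatment_ps`,
`stabilized_iptw`, `fit_participation_ps`, `iopw_compose`, `balance_table`,
`tipton_index`, `impute_chained`, `pool_rubin`, `fit_weighted_cox`,
`ph_test`, `km_weighted`, `derive_endpoint`), and through the `iopw` command
line (`simulate`, `impute`, `weights`, `balance`, `fit`, `step1`, `step2`,
`report`).

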