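# Methods

## Estimands and weighting model

The package estimates two marginal hazard ratios for a binary treatment
*A* on a right-censored time-to-event outcome:

* in the **original cohort** (*S* = 1), after removing confounding by
  measured baseline covariates *C*, and
* in a **target population** (*S* = 0) whose effect-modifier distribution
  differs from the original cohort's, by additionally reweighting the
  original cohort to resemble the target.

Step 1 uses stabilized inverse probability of treatment weights
*W = A·P(A=1)/P + (1−A)·P(A=0)/(1−P)* with *P = P(A=1|C)* from a
main-effects logistic regression fitted on original-cohort rows only.
Stabilization by the marginal treatment probability (estimated as the
observed treated fraction) leaves the estimand unchanged while keeping the
weight variance down; the mean stabilized weight is ≈ 1 under a correctly
specified model.

Step 2 composes *V = W · (1−Q)/Q · P(S=1)/P(S=0)* with
*Q = P(S=1|E)* from a main-effects logistic regression of cohort membership
on the effect modifiers over the combined rows, and the marginal odds
estimated as *n₁/n₂*. *Q* is the probability of membership in the
**original** cohort, so *(1−Q)/Q* is the inverse odds of participation: it
down-weights original patients over-represented relative to the target.
Target rows receive *V = 0* — they inform the participation model but carry
no weight in the outcome model. The outcome model in both steps is a
weighted Cox partial likelihood with treatment as the only covariate
(Efron tie handling), a robust sandwich variance (correct under weighting),
and a Schoenfeld-residual proportional-hazards test using the Kaplan–Meier
time transform. Both the point estimate and the robust SE are invariant to
rescaling all weights by a constant.

Identification requires the usual assumptions: no unmeasured confounding
given *C*, positivity of both propensities, conditional exchangeability of
cohort membership given *E*, and a shared outcome-generating mechanism
across cohorts. None of these is testable from the data; the diagnostics
below only check the parts that are observable.

## Diagnostics

**Standardized mean differences.** Continuous:
|m₂ − m₁| / √((s₁² + s₂²)/2). Binary: |p₂ − p₁| / √((p₁(1−p₁) + p₂(1−p₂))/2).
Categorical (K ≥ 3): the multinomial Mahalanobis distance
√(Tᵀ S⁻¹ T) over K−1 category proportions with S the average multinomial
covariance (Yang–Dalton convention); it reduces algebraically to the binary
formula at K = 2, and zero-frequency categories are dropped before
inversion. Proportions are computed over non-missing values only — this
convention reproduces the published percentages the test suite anchors on,
and the 4-level race row of the published arm-comparison table (0.133)
recomputes exactly under Yang–Dalton, validating the choice. Weighted SMDs
substitute weighted moments (normalized weights within group). The 0.1
flagging threshold is the field convention and is configurable.

**Tipton index.** The published definition of the similarity integral is a
plain product ∫f(p₁)f(p₂)dp, which is not bounded by 1; the package
implements the Bhattacharyya coefficient ∫√(f₁ f₂)dp from the underlying
generalizability literature, which is. Densities are Gaussian KDEs with
Silverman bandwidth evaluated on a 512-point grid padded 4 bandwidths past
the data range, integrated by the trapezoid rule, computed on the logit
score scale by default (`scale="probability"` is available). Identical
samples give 1 within 1e−6; two unit-variance Gaussian score populations a
mean apart give e^(−1/8) ≈ 0.8825, which the KDE version reproduces within
0.02 at n of a few thousand.

## Missing covariates

Missingness is confined to covariates; treatment, outcome and cohort
membership must be complete. The strategy is impute-first/derive-after
(raw covariates are imputed, propensity scores are *always* recomputed
inside each completed dataset) with the whole weighting-plus-outcome
analysis run within each imputation — the pipeline API only exposes
per-imputation execution, so this is enforced structurally rather than by
convention.

The chained-equations sampler visits covariates in order of increasing
missingness for 10 burn-in sweeps (configurable). Component models:
predictive-mean matching with 5 donors for continuous covariates,
multinomial/logistic draws for categorical and binary ones (predictors
standardized internally for solver stability). Parameter uncertainty is
propagated by refitting each component model on a bootstrap resample of the
observed rows at every update — a standard approximation to posterior
draws that is robust to separation and rank deficiency in small strata.
Predictors for each target covariate are all other covariates
(categorical ones one-hot), the cohort indicator *S*, and — zeroed on
target rows, with the *S* main effect absorbing the offset — treatment,
the event indicator and log(1 + time) as the outcome's representation
(a standard proxy for the cumulative hazard). m defaults to 20.

Per-imputation log hazard ratios (with robust SEs) are pooled by Rubin's
rules: pooled estimate = mean; total variance = within + (1 + 1/m)·between;
degrees of freedom by the classic (m−1)(1 + W̄/((1+1/m)B))² formula with a
normal reference when m = 1 or B = 0. Balance tables are summarized as
median (min, max) across imputations and the Tipton index as mean ± SD.
The stabilization constants are recomputed per imputation; since treatment
and cohort sizes are never missing they are in fact constant across
imputations.

## Synthetic cohorts and the marginal-HR oracle

The generator realizes the causal structure the method addresses:
covariates confound treatment (logistic assignment with user coefficients),
affect the hazard, and optionally modify the treatment effect
(A×E interaction log-hazard terms); the same modifiers drive selection into
the original cohort. Event times are inverse-transform draws from
H(t) = λ₀·t^k·exp(lp) — exponential by default (k = 1), Weibull optional —
with administrative-horizon plus independent exponential censoring.
Missingness is imposed MCAR or MAR with rates keyed to levels of a fully
observed column (dependence on a variable that itself has missingness is
rejected so the mechanism stays verifiable). A single seed is split into
named substreams (covariates, selection, assignment, outcome, censoring,
missingness), so identical configs and seeds give byte-identical tables and
stages can be replayed independently.

Two generation modes cover the two ways a cohort contrast can be specified.
With per-cohort marginals (default) the generator draws exactly
`n_original` and `n_target` rows from cohort-specific covariate
distributions. With an explicit logistic selection model it draws a pool of
`n_original + n_target` rows from the base distribution and assigns *S* by
Bernoulli draws, so a logistic refit of *S* on *E* recovers the selection
coefficients exactly in expectation; realized cohort sizes are then
binomial around their targets — exact sizes and an exactly-held selection
model cannot coexist, and the package prefers the verifiable mechanism when
one is requested.

Because the Cox hazard ratio is non-collapsible, the marginal HR in a
population has no closed form once covariates affect the hazard. The
package therefore defines the estimand by a counterfactual Monte-Carlo
oracle: draw covariates from the population of interest, simulate *both*
potential uncensored event times (A set to 1 and to 0 for every draw), and
fit a treatment-only Cox model to the stacked counterfactual data
(default 2×10⁵ draws). With no effect modification the oracle agrees across
populations up to Monte-Carlo error; with no covariate effects on the
hazard it equals exp(β_A).

The bundled `table_like_config` emulates a two-line oncology registry:
Normal age, 4-level race/stage/ECOG, binary visceral and bone-only disease
and practice type, with cohort-specific marginals, treatment confounded by
age/stage/ECOG/visceral status, an exponential progression-free-survival
hazard (λ₀ = 1.6×10⁻³/day, i.e. ≈ 14-month median at the baseline linear
predictor) over a 3-year horizon, and MAR-free default missingness of
5.5%/7.5%/29% on race/stage/ECOG. One deliberate deviation from the
emulated tables: the real first-line population contains *no* ECOG ≥ 3
patients (an eligibility criterion), but a structural zero at a level
present in the original cohort quasi-separates the participation model, so
the default keeps 1% mass at the top ECOG level. What the generator does
*not* emulate: EHR-derived coding artifacts, informative censoring,
time-varying covariates, correlation between covariates beyond what the
outcome/selection models induce, and unmeasured confounding — so passing
parameter-recovery tests demonstrates correctness of the estimators under
the stated assumptions, not robustness to their violation.

## Endpoint derivation

For date-level inputs, the index date is therapy start + 14 days (no
immediate treatment effect expected). An event is the earliest documented
progression or death; death dates are known to month granularity and set to
the 15th. Censoring is at the last clinical note or index + 1095 days (3
years = 3×365), whichever is earlier. Patients whose earliest event falls
*on or before* the index date are excluded with a reason flag rather than
dropped silently ("on" as well as "before" because a time of zero is not a
valid survival time); a recorded death month resolving to before therapy
start is likewise flagged as a data anomaly. Ties between progression and
death on the same date resolve to progression.

## Numerical and design choices

* Propensity models: main effects only, continuous covariates linear,
  categorical covariates as reference-coded indicators. Perfect or
  quasi-complete separation (fitted probabilities within 1e−10 of 0/1, or
  optimizer failure) raises an explicit `SeparationError` naming offending
  rows rather than returning extreme weights.
* Weight truncation is off by default (symmetric percentile truncation is
  available behind a flag and recorded in the weight provenance); zero
  step-2 weights on target rows are never truncated away.
* Zero-weight rows are dropped before Cox fitting; the robust SE, not the
  model-based SE, is reported in all pooled results.
* Simulation sizes in the test suite are scaled to desk scale as the
  package's own verification budget: parameter-recovery experiments at
  n = 5×10³ with 8×10⁴-draw oracles, the MI coverage experiment at 200
  replicates of n = 400 with m = 10, and PH-test calibration/power at 200
  replicates of n = 600 / n = 2×10³.

## Known limitations

* The participation model is logistic with linear terms; when the true
  selection log-odds is non-linear in a modifier (e.g. cohorts differing in
  variance, not just mean), residual imbalance can remain after weighting —
  the balance table is the guard, not the model itself.
* The bootstrap-refit approximation in the imputer slightly underestimates
  parameter uncertainty relative to a fully Bayesian draw; the coverage
  experiment bounds the practical effect.
* The oracle defines the marginal HR from uncensored counterfactuals; under
  heavy covariate effects the censored analysis targets a slightly
  different time-averaged quantity (the HR is non-proportional marginally),
  which is visible only as a small bias at very large n.
* No doubly robust augmentation and no machine-learning propensity models;
  both steps are plain logistic + weighted Cox by design.
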