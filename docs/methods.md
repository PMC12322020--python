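# Methods

This note documents the statistical procedures the package implements, the
synthetic-cohort model behind the tests, the defaults and the numerical
choices, in enough detail to audit or re-derive them.

## 1. Measures and case definitions

Six instruments are encoded in a YAML registry (`drmediate/data/scales.yaml`):
the SDQ hyperactivity/inattention subscale (5 items, 0–2 each, total 0–10; the
exposure), a nine-item problematic-gaming symptom count (0–9; the mediator),
the SMFQ (13 items, total 0–26), a 14-item CBCL anxiety subset (0–28), the
APSS (7 items scored 0/0.5/1, total 0–7) and the WHO-5 (5 items 0–5, sum
multiplied by 4, total 0–100; higher is better).  Totals are plain item sums;
missing items are never prorated — incomplete cells are resolved upstream by
imputation of totals.

Case definitions: high gaming = score ≥ 4; depression = SMFQ ≥ 8; anxiety =
T-score ≥ 65 where T = 50 + 10(x − μ)/σ; psychotic experiences = at least one
"yes, definitely" (1.0) APSS item; diminished well-being = WHO-5 ≤ 50.
Three conventions were genuinely open and are resolved as follows:

* **WHO-5 boundary**: diminished iff score ≤ 50 (a `who5_strict` flag gives
  `<` instead).
* **Anxiety T reference**: computed from the analysis sample itself,
  gender-specific, at the outcome wave; no external norm table is assumed.
* **APSS case from totals**: the definite-item rule is not identifiable from a
  half-point total alone (two "maybe" responses also sum to 1.0), so when only
  totals are available the convention is case iff total ≥ 1.0;
  `dichotomize_outcome` applies the exact any-item-equals-1 rule whenever an
  item matrix is supplied.

"Incident" outcomes are operationalized as wave-3 case status with the wave-1
continuous score entered as a covariate, not by excluding baseline cases.

Cronbach's alpha is the classical (k/(k−1))(1 − Σ var(itemᵢ)/var(total)) with
ddof = 1; zero total variance is signaled as undefined.

## 2. Synthetic cohort model

`generate_cohort` draws twelve wave-1 covariates from fixed marginals matched
to published cohort summaries (e.g. IQ ~ N(110, 14.9²), income a 3-level
ordinal with probabilities 0.184/0.535/0.281, problematic internet use a
gamma with mean 3.94 and SD 4.16 snapped to an integer 0–33 grid).  The
structural equations, on a latent continuous scale, are

    A  = βₐ0 + βₐᵀz + εₐ                             (exposure, 0–10)
    M  = α₀ + α₁ A + αᵀz + ε_m                       (mediator, 0–9)
    Y₁ = μ₁ + γᵀz + ε₁                               (baseline outcome)
    Y₃ = θ₀ + θ₁A + θ₂M + θ₃AM + γᵀz + λ(Y₁ − μ₁) + ε₃

where z are the covariates standardized by their *target* (not sample)
marginals, so coefficients are per covariate SD and the closed-form truths do
not depend on sampling noise in the standardization.  Scores are then
rounded half-up to each instrument's grid and clipped to its range
(`discretize=False` returns the latent values).

Defaults are chosen so the latent per-1-SD effects sit on the scale of the
published mediation estimates: α₁ = 0.08 mediator units per exposure unit
(≈ 0.18 per exposure SD), θ-vectors per outcome giving total effects of ~0.25
(SMFQ), ~0.3 (anxiety), ~0.06 (APSS) and ~−1.3 (WHO-5) per exposure SD with
indirect shares of roughly 10–30%, carryover λ = 0.35, and noise SDs that
reproduce the published score SDs (e.g. SMFQ 4.49).  Default missingness rates
follow the published per-variable missing fractions (5–23% at wave 1; 15.9%
for the mediator wave and 17.5% for the outcome wave, the cohort's follow-up
losses).

**Missingness mechanisms.**  MCAR blanks cells independently.
MAR-on-observed shifts each variable's missingness logit by 0.4·z(gender) +
0.4·z(exposure), centered so the marginal rate stays close to the nominal one;
gender and the exposure score themselves are blanked MCAR (and age kept MCAR)
so the conditioning variables of the mechanism remain observed and the
imputation model's assumptions are satisfiable.

**Closed-form truths.**  On the latent scale
PDE = (θ₁ + θ₃E[M|a₀, c̄])(a₁ − a₀), TIE = (θ₂ + θ₃a₁)α₁(a₁ − a₀),
TE = PDE + TIE exactly.  After discretization these are only approximate:
rounding the mediator attenuates θ₂ slightly (errors-in-variables) and
clipping at the scale floor censors the most-affected outcome scores, which
biases the *direct*-effect estimate on heavily clipped scales (SMFQ loses
~10% of its latent mass below 0 under the defaults) while the indirect effect
survives nearly intact.  Recovery and coverage tests therefore run on the
latent scale, with a separate wide-tolerance check on discretized data.

**Binary-treatment companion generator.**  `generate_dr_cohort` draws the same
covariates, assigns a binary treatment from a logistic propensity and a binary
outcome from a logistic outcome model, and returns exact marginal
counterfactual risks (the cohort means of the outcome-model probabilities with
treatment forced to 1 and 0).  It exists so that coverage claims about the
doubly robust estimator are evaluated under a correctly specified model
family; on the thresholded-Gaussian cohort scores the logistic working models
are mildly misspecified by family, which is realistic but makes sharp
unbiasedness claims inappropriate there.

What the generator does **not** emulate: the real cohort's joint covariate
dependence (covariates are drawn independently), zero-inflation and skew of
symptom scales beyond what thresholded Gaussians produce, attrition as a
longitudinal process, and item-level response patterns (totals are generated
directly).  Passing tests therefore demonstrate estimator correctness under
the assumed structural model, not fidelity to any particular cohort.

## 3. Imputation

`rf_impute` is an iterative random-forest imputer: initialize missing cells
with observed means/modes, cycle variables in ascending missingness order,
regress each on all others with a random forest (classifier for binary
variables, regressor otherwise) trained on observed rows, and replace the
missing cells with predictions snapped to the variable's grid and range.
Iteration stops at the first rise in the difference statistic
Σ(Xnew − Xold)²/ΣXnew² (continuous) or the fraction of changed categories
(categorical), returning the previous iteration's values, or after
`max_iterations`.  Defaults: 100 trees, 10 iterations, single imputation run
once upstream of all analyses with every analysis variable (outcomes included)
in the model.  Observed cells are never modified; determinism follows from a
per-variable seed stream derived from the config seed.

## 4. Association models

Three nested tiers: Model 1 unadjusted; Model 2 adds age, gender, BMI, IQ,
household income; Model 3 adds loneliness, physical punishment, relationships
with mother/father/friends, neighborhood cohesion, gender nonconformity, plus
— for mediator→outcome models — the exposure score and all four baseline
mental-health scores, or — for the exposure→mediator model — baseline
gaming time and problematic internet use.  Continuous-exposure coefficients
are reported per 1 SD of the exposure, computed on the completed overall
sample; stratified fits reuse the overall SD (and drop the stratifier from the
roster) so per-SD estimates stay comparable across strata.  Note the Model-3
roster for mediator→outcome mirrors the published adjustment set, which omits
baseline gaming-time/internet-use; under the generator's defaults that leaves
deliberate residual confounding of the mediator→outcome association (the
fully adjusted mediation roster closes it).

Risk ratios for binary outcomes use modified Poisson regression: log-link
Poisson with HC0 sandwich standard errors, the standard device for valid RR
inference on binary data (a plain Poisson variance would be wrong there).

## 5. Doubly robust estimation

`fit_propensity` fits a logistic treatment model and returns unstabilized
weights 1/e, 1/(1−e).  `dr_standardize` fits a weighted logistic outcome model
(treatment + roster), predicts every subject's risk under both treatment
assignments and averages over the full sample; with `weights=None` it is the
plain g-formula.  Consistency under either correct model is verified
empirically in the tests (bias within Monte-Carlo error when exactly one of
the two models omits a nonlinear confounder term, and visible bias when both
do).

Numerical choices: the IRLS logistic solver clips linear predictors at ±35 so
separated fits saturate instead of overflowing; quasi-separation (any fitted
propensity within 1e-8 of 0/1) is signaled with the affected subject count.
By default there is no weight truncation; an optional percentile-truncation
flag clips weights (and then also clips propensities instead of raising on
separation), intended for small samples where the full roster is rich relative
to the number of treated subjects.  Bootstrap CIs are percentile intervals
over subject resamples, rerunning propensity and outcome stages per replicate;
replicates that fail (separation, empty arm, undefined ratio) are dropped and
counted, escalating to an error beyond 10% drops.  The bootstrap resamples the
completed (post-imputation) table; re-running imputation inside every
replicate is out of scope for runtime and documented as a limitation.

Interaction: joint treatment × gender risks are standardized from a weighted
logistic model with a product term, each category's risk being the sample
average of predictions with (treatment, gender) forced; RERI and RRR follow
from the three risk ratios against the common reference, which defaults to
(untreated, boys) and is configurable.  E-values use RR + √(RR(RR−1)) after
inverting protective ratios, with the CI E-value computed from the bound
closer to 1 and set to 1 when the interval crosses 1.

## 6. Mediation

Both models are OLS fits on the completed table with retained coefficient
covariances; the outcome model always carries the exposure×mediator product.
The decomposition is evaluated at the covariate sample mean c̄ (equivalent to
averaging over the empirical covariate distribution in linear models) for the
contrast a₀ = sample mean of the exposure, a₁ = mean + 1 SD, both computed on
the completed overall sample and held fixed (treated as constants, not
estimated quantities) in the delta method.  Delta-method variances use
block-diagonal covariance across the two models (independently fitted);
with θ₃ = 0 the TIE standard error reduces exactly to the Sobel formula.
Gender-stratified mediation refits both models within stratum (dropping gender
from the roster) while keeping the overall a₀/a₁.  The proportion mediated
TIE/TE is reported as a percentage and flagged as unstable when TE and TIE
have opposite signs or TE ≈ 0.  The Monte-Carlo counterfactual oracle draws
M(a₀), M(a₁) from the mediator model's Gaussian law and pushes them through
the outcome model; for these linear models it must agree with the closed forms
up to Monte-Carlo error, which is the defining cross-check in the tests.

## 7. Pipeline, determinism and problem sizes

The pipeline (library functions or the `drmediate` CLI) runs simulate →
impute → score → associate → dr → mediate, writing CSV/TSV/JSON artifacts and
a manifest with a config hash, so identical configs give byte-identical
outputs; every stochastic stage takes an explicit seed.  Exit codes: 0
success, 2 configuration error, 3 stage failure (with the stage named).

Simulation studies in the test suite use sizes chosen to make their claims
sharp at desk scale: parameter-recovery and coverage studies run 100 cohorts
of n = 3000 (500 bootstrap replicates for the doubly robust CIs), the
double-robustness study 150 simulations of n = 2000 per misspecification
scenario, and the null-effect type-I study 50 pipeline cohorts at the study
scale n = 3171 with 300 bootstrap replicates (percentile intervals are
visibly anti-conservative at a few hundred subjects with ~9% treated, which
is itself documented behavior of the percentile bootstrap rather than a
defect of the estimator).

## 8. Known limitations

* Single imputation; no Rubin-style between-imputation variance, no MNAR
  sensitivity analysis.
* Bootstrap CIs condition on the completed table (imputation uncertainty not
  propagated).
* Mediation treats mediator and outcome as continuous; no odds-ratio-scale
  decomposition for rare binary outcomes, single mediator only, two-way
  decomposition only.
* The E-value addresses unmeasured exposure–outcome confounding of the DR
  estimates; no analogous sensitivity analysis is provided for the
  mediator–outcome confounding assumptions of the mediation model.
* Closed-form truths are exact only on the latent scale; discretized-scale
  estimates of direct effects on heavily clipped scales are attenuated (see
  §2).
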