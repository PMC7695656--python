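# Methods

This note documents the statistical machinery in `dietnafld`, the default
parameter choices and why they were made, what the synthetic-data generator
does and does not emulate, and known limitations.

## The scientific setting

The package targets longitudinal population cohorts in which diet is
measured by semi-quantitative FFQ at repeated visits and hepatic steatosis
is assessed by ultrasound, with transient elastography (liver stiffness,
kPa) as a fibrosis proxy. Dietary quality is summarized two ways: *a
priori* indices with fixed components and thresholds (MDS, Dutch
guidelines, WHO recommendations) and *a posteriori* patterns derived from
the data by factor analysis. The analysis question is whether adherence to
any of these patterns predicts presence, incidence or regression of
steatosis over follow-up, net of sociodemographic, lifestyle and metabolic
confounders.

## Eligibility and phenotype

Rules are applied in a fixed cascade (missing ultrasound → FFQ reliability
→ TE reliability → TE failure → viral hepatitis → alcohol misuse →
steatogenic drugs → intracardiac device → high stiffness without
steatosis), and an excluded participant is attributed to the *first*
failing rule, so the tally reads like a study flowchart. Boundary semantics
follow the printed definitions exactly: energy reliable on the closed
interval [500, 7500] kcal/day; TE unreliable when IQR/median > 0.30 *and*
the median is ≥ 7.1 kPa; misuse at ≥ 2 (women) / ≥ 3 (men) units/day, one
unit = 10 g ethanol (a convention this package fixes because FFQ-derived
"units" are otherwise undefined); NASF = steatosis with stiffness ≥ 8 kPa.
A steatosis-positive participant with missing stiffness is retained as
NAFLD with an explicit flag, because dropping them would bias prevalence
while promoting them to NASF would overstate fibrosis. Classification is
total: every (steatosis, stiffness) pair maps to exactly one phenotype.

## A priori scores

* **MDS (0–8).** Seven beneficial components (vegetables, legumes, fruit,
  nuts, whole grains, fish, MUFA:SFA ratio) score 1 at or above the
  sex-specific baseline median (the "at or above" convention follows the
  original Mediterranean-score construction); red meat scores 1 strictly
  below its median. The classical alcohol component is excluded — in a
  hepatic context alcohol belongs among the confounders, not in the
  exposure. Cut-offs are computed on the baseline visit only and reused at
  follow-up.
* **DDG (0–14)** and **WHO (0–6)** use absolute printed thresholds, stored
  in `data/score_thresholds.yaml` so that alternative guideline editions
  are configuration, not code. Decisions the definitions leave open, fixed
  here once: ratio components (whole-grain share, unsaturated-fat share)
  score 0 when the denominator is zero — undefined adherence is not
  rewarded; the unsaturated-fat share is computed nutrient-side as
  (MUFA+PUFA)/total fat; salt is derived from sodium as g salt = 2.54 × g
  sodium (molar-mass ratio of NaCl to Na), with discretionary salt not
  modelled; the WHO sugar criterion is implemented as the absolute
  "< 10 g/day added sugar" threshold with the value configurable; the
  MUFA:SFA ratio with zero SFA is +∞ (scores 1) unless MUFA is also zero
  (scores 0). Some published cohort tables print different ranges for
  these indices (e.g. 0–10 / 0–13 / 0–5); this package implements the
  component definitions (8/14/6) and treats such range statements as
  typographic.
* Missing component inputs never silently score 0: the indicator becomes
  `None` and the total is flagged incomplete. Imputation is the
  association module's job.

## A posteriori patterns

Factor analysis runs on the **correlation** matrix of the 28 raw g/day
intakes — intakes span three orders of magnitude, so covariance-based
analysis would be dominated by coffee and dairy volume. Extraction is
minimum-residual (minres/ULS): loadings minimize the sum of squared
off-diagonal residuals of `R − ΛΛ′`. The implementation optimizes the
uniquenesses ψ by L-BFGS-B (bounds [0.005, 1], started from 1 − squared
multiple correlation, which makes the solution deterministic); given ψ the
loadings are the top-k eigenstructure of `R − diag(ψ)`. On random
6×6 problems the objective agrees with a free-parameter quasi-Newton
optimum to ~1e−15 provided the solution is interior (a pinned ψ — a
Heywood case — changes the estimand, which is why the solution reports
uniquenesses for inspection).

Varimax rotation is the classical Kaiser-normalized SVD iteration;
orthogonality preserves communalities and `ΛΛ′` exactly (drift ≤ 1e−10 in
the validation suite). Columns are re-sorted by explained variance, and
each column's sign is fixed so its largest-magnitude loading is positive.

Factor retention reports the full scree table and suggests k by maximum
curvature (largest second difference of the sorted eigenvalues); the bend
is flagged "unclear" when the winning curvature is less than twice the
runner-up. The replication configuration overrides the heuristic with
k = 5. A |loading| > 0.2 threshold marks the groups "defining" a pattern.

Adherence scores multiply the loadings with the **raw observed** intakes
(`Λ′x`), are standardized to mean 0 / SD 1 on the baseline sample, and the
same scaling parameters are applied to follow-up scores so that change over
time is interpretable. Whether the food groups should be z-scored before
multiplication is genuinely ambiguous in the field; both modes exist
(`standardize_inputs=True`), with raw intakes as the default.

Recovered factors are matched to a reference by Hungarian assignment on
absolute Tucker congruence followed by sign alignment. The bundled 28×5
reference loading matrix reproduces a published elderly-cohort pattern
structure (vegetable-and-fish, red-meat-and-alcohol, traditional,
salty-snacks-and-sauces, high-fat-dairy-and-refined-grains); where the
source table's layout left a sub-threshold entry's column ambiguous, the
assignment follows the published narrative description of each pattern and
the |loading| > 0.2 bolding rule. Column sums of squared loadings give
explained-variance shares of 4.7/4.1/4.2/3.2/2.5% (≈19% jointly), matching
the structure it emulates.

## Nutrient profiling

Energy adjustment uses the residual method: a nutrient is regressed on
total energy by OLS and replaced by residual + prediction-at-mean-energy,
which keeps the original scale and is *exactly* uncorrelated with energy
(OLS orthogonality). "Adjusted Spearman" correlations are Spearman
correlations of the residualized raw values — this matches the
residual-method language of the workflow the package implements; a
rank-based partial correlation is available behind `method="partial"`
because the two readings are not equivalent and published figures rarely
say which was used. Ties receive average ranks; profiling is complete-case
(n is reported per cell, and fewer than 3 complete pairs yields an absent,
not zero, coefficient).

## Bayesian mixed models with simultaneous imputation

The outcome model is a random-intercept logistic regression (Gaussian
variant for BMI as outcome). Two covariate sets mirror the usual
confounder strategy; diet exposures enter time-varying, the a priori
scores one at a time, the five a posteriori scores jointly (they are
nearly orthogonal by construction). Covariates labelled baseline are
carried forward to follow-up rows.

*Priors.* Continuous covariates are standardized internally; coefficients
get N(0, 10²) priors on that scale (effectively non-informative),
the random-intercept SD a half-normal(2.5), and the Gaussian residual
variance an inverse-gamma(0.01, 0.01). Coefficients are reported
back-transformed to original units, so e.g. energy intake appears as an OR
per kcal.

*Sampler.* Adaptive Metropolis-within-Gibbs, chosen for having no
compiled-model build step and exact control over the imputation blocks:

* a joint adaptive random-walk update of β (Haario-style empirical
  covariance, adapted during burn-in only);
* a componentwise β sweep with per-coordinate scales;
* vectorized single-site updates of all random intercepts (conditionally
  independent given β, τ);
* two classes of likelihood-aware joint moves that decorrelate the slow
  directions of hierarchical logistic models: an intercept↔random-effects
  shift, and per-covariate shifts along each column's participant-mean
  direction (only within-participant deviations inform the acceptance
  ratio, so these moves take large steps);
* τ by random-walk on log τ; Gaussian σ² by conjugate Gibbs.

Split-Rhat and effective sample size come from ArviZ; `strict` mode turns
Rhat ≥ 1.1 into an error. Two chains and 2 500–4 000 iterations are
adequate for the model sizes in the validation suite; calibration was
verified by simulation (95% credible intervals for a zero-effect exposure
exclude the null in ≈5% of 200 replicates).

*Missing covariates.* Incomplete covariates are treated as participant-
level unknowns with conditional models in a sequential factorization
(ordered by rising missingness): continuous → linear (conjugate Gibbs for
its parameters), binary → logistic, ordered categorical → cumulative
logit (random-walk MH). Predictors are the complete covariates of the
extensive set plus earlier incomplete covariates. A missing value's full
conditional combines its covariate model, any later covariate models it
feeds, and the outcome likelihood of the participant's rows; values are
updated by vectorized MH (random-walk / category flip). Outcomes and
exposures are never imputed — a missing exposure is a hard error. Which
covariates are incomplete, and their families, are auto-detected but fully
overridable via `ImputationSpec`.

*Pooling.* The reduced-model workflow extracts m = 10 equally spaced
post-burn-in draws of the missing-value block, refits the reduced model on
each completed dataset, and pools by mixing the chains with equal weight —
exact for posterior summaries of the equal-weight mixture, with no
normality assumption (unlike Rubin's rules). Interaction screening labels
a term relevant when its 95% credible interval excludes 0 and its tail
probability (2 × the smaller tail mass at 0, floored at 1/draws) is
below 0.05, then refits without interactions reusing the original
imputations.

The univariable food-group screen is deliberately frequentist (statsmodels
logistic regression of baseline steatosis on each energy-adjusted,
SD-standardized group): it is a descriptive supplement, and the simple GLM
is also the independent cross-check for the MCMC in the degenerate
zero-random-intercept case.

## The synthetic-data generator

`SimConfig` defaults *are* the emulated study conditions: 963 participants,
two visits 4.4 years apart, 35.6% baseline steatosis prevalence, 23.5%
loss to follow-up (completely at random), missingness 2.7% education /
7.1% physical activity / 5.7% smoking, and the bundled 5-factor loading
structure. Food groups arise as `X = ΛF + ε` with standard-normal latent
factors (autocorrelation 0.6 between visits) and uniqueness-scaled noise;
`linear` mode returns these standardized values (sample correlation
converges to `ΛΛ′ + Ψ`, used by the recovery tests), while `positive` mode
pushes them through a per-group softplus calibrated to the reference
median/IQR intakes — strictly positive and median-matched, but a nonlinear
distortion under which exact loading recovery is not expected. Nutrients
are a fixed per-gram composition matrix (editable CSV config, plausible but
not asserted nutritionally accurate) times the food groups, with 5%
lognormal noise. Steatosis comes from the logistic random-intercept model
itself; the intercept is calibrated by Gauss–Hermite quadrature so the
*marginal* baseline prevalence equals the configured target, and the
negative follow-up-time coefficient (OR 0.74/year by default) produces the
regression-exceeds-incidence asymmetry seen in elderly cohorts. Default
random-intercept SD is 1.0 — enough persistence to make steatosis sticky
without degenerating the logistic fit. Liver stiffness is lognormal
(median ≈ 4.9 kPa, shifted upward under steatosis so ~9–10% of steatosis
crosses 8 kPa).

What the generator does **not** emulate: item-level (389-item) FFQ
structure (only the 28-group level is generated; the item→group map is
supported as configuration for real data); informative (MNAR) dropout —
only MCAR dropout and MAR covariate missingness are available, so analyses
of robustness to informative loss to follow-up are out of reach by design;
calibrated transition rates — the regression/incidence asymmetry is
qualitative, its magnitude depends on the random-intercept SD and covariate
effects rather than being tuned to any published percentage; measurement
error in ultrasound or FFQ beyond what the noise terms imply. Passing
recovery tests on these cohorts therefore demonstrates correctness of the
estimation machinery under the stated generative model, not robustness to
every failure mode of real dietary data.

## Numerical conventions and problem sizes

Tolerances: correlation-matrix validation at 1e−6 symmetry/PSD; minres
L-BFGS-B `ftol` 1e−14; varimax convergence 1e−12; adherence standardization
uses the population (ddof = 0) SD so baseline scores are *exactly* mean 0 /
SD 1. Ties in Spearman ranks are averaged. Degenerate inputs error loudly
and early (zero-variance energy, empty sex strata, over-factored requests,
non-positive scaling SDs) rather than propagating NaN.

The validation suite sizes its simulations for precision at interactive
cost: n = 50 000 for covariance convergence (elementwise tolerance 0.02),
n = 20 000 for factor recovery (Tucker congruence ≥ 0.95 per factor),
n = 1000 for odds-ratio recovery, and 200 replicates at n = 250 with
shortened chains for null credible-interval calibration (binomial SE ≈
1.5 points at the 5% nominal rate).

## Known limitations

* The MCMC is random-walk based; models far larger than the cohort sizes
  here (tens of covariates, tens of thousands of rows) would warrant a
  gradient-based sampler.
* The random-intercept SD is weakly identified by two binary observations
  per participant; its posterior mean sits above a small true value at
  these sample sizes (fixed-effect inference is unaffected — verified
  against the GLM limit).
* The cumulative-logit imputation model updates its cut-points and
  coefficients jointly by random-walk MH, which is adequate for the
  three-level education variable but would mix slowly for many categories.
* Factor-analysis standard errors are not provided; the recovery tests
  quantify stability by simulation instead.
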