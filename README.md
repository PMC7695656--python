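# dietnafld

Dietary-pattern analysis for cohort studies of non-alcoholic fatty liver
disease (NAFLD). The package is aimed at nutritional epidemiologists who
have participant-visit tables with food-frequency-questionnaire (FFQ)
food-group intakes, nutrient totals, and hepatic imaging readouts
(ultrasound steatosis and transient-elastography liver stiffness), and who
want to relate overall dietary quality — rather than single nutrients — to
liver phenotype over time.

## What it does

1. **Eligibility filtering** — the classic screening cascade for an
   FFQ/elastography cohort: missing ultrasound, unreliable FFQ
   (energy outside [500, 7500] kcal/day), unreliable or failed transient
   elastography (IQR/median > 0.30 at a median ≥ 7.1 kPa; no reading after
   ≥ 10 attempts), viral hepatitis, alcohol misuse (≥ 2 units/day women,
   ≥ 3 men), steatogenic drugs, intracardiac devices, and high liver
   stiffness (≥ 8 kPa) without steatosis. Steatosis with stiffness ≥ 8 kPa
   is classified as steatofibrosis (NASF).
2. **A priori diet-quality scores** — an adapted 8-component Mediterranean
   Diet Score (sex-specific median cut-offs, alcohol excluded), the
   14-component Dutch Dietary Guidelines score, and the 6-component WHO
   recommendation score, from a canonical 28-food-group schema.
3. **A posteriori dietary patterns** — exploratory factor analysis of the
   28 food groups: minimum-residual (minres) extraction on the correlation
   matrix, varimax rotation, scree-based factor retention (k = 5 in the
   replication configuration), and standardized adherence scores whose
   baseline scaling is reused at follow-up.
4. **Nutrient profiling** — Willett residual-method energy adjustment and
   Spearman correlation profiles of pattern adherence against macro- and
   micronutrients (unadjusted / energy-adjusted / energy-plus-patterns
   adjusted).
5. **Association models** — Bayesian random-intercept logistic regression
   of steatosis on diet scores with missing covariates imputed *inside* the
   MCMC (normal / logistic / cumulative-logit conditional models), the
   extract-10-imputations-and-pool workflow for the reduced covariate set,
   interaction screening, BMI-as-outcome linear mixed models, and a
   univariable energy-adjusted food-group screen.
6. **Synthetic cohorts** — a seed-reproducible generator that emulates the
   structure above (latent 5-factor food-group correlations, two visits
   4.4 years apart, ~35.6% baseline steatosis, MAR covariate missingness,
   ~23.5% loss to follow-up) together with the ground truth used to build
   it, so every stage can be validated by parameter recovery.

The model at the core is

```
y_ij ~ Bernoulli(expit(x_ij' β + b_i)),   b_i ~ N(0, τ²)
```

for participant *i* at visit *j*, with diet exposures entering
time-varying, confounders in two nested sets ("model 1": sex, baseline age,
education, physical activity, energy, alcohol, follow-up time; "model 2":
additionally BMI, diabetes, hypertension), wide normal priors on β, a
half-normal prior on τ, and missing covariate values sampled jointly with
the coefficients.

## Worked example

```python
import numpy as np
from dietnafld import (SimConfig, generate_cohort, apply_exclusions,
                       DietaryPatternFA, adherence_scores, score_cohort,
                       BayesLogisticMixedModel, ModelSpec)
from dietnafld.foodgroups import FOOD_GROUPS

cohort, truth = generate_cohort(SimConfig(n_participants=963, seed=1))
baseline = cohort[cohort.visit == 1]
eligible, tally = apply_exclusions(baseline)
print(len(baseline), "->", len(eligible), "eligible;",
      f"{100*eligible.steatosis.mean():.1f}% steatosis")

fa = DietaryPatternFA(n_factors=5).fit(eligible[list(FOOD_GROUPS)])
print(fa.explained_variance_share.round(2).to_dict())

scores, scaling = adherence_scores(fa.loadings, eligible[list(FOOD_GROUPS)])
print(scores.mean().round(6).to_dict())  # exactly 0 at baseline by construction
```

prints (seed 1):

```
963 -> 890 eligible; 36.9% steatosis
{'factor1': 4.26, 'factor2': 4.04, 'factor3': 3.91, 'factor4': 3.59, 'factor5': 3.31}
{'factor1': 0.0, 'factor2': 0.0, 'factor3': -0.0, 'factor4': 0.0, 'factor5': -0.0}
```

i.e. under a tenth of the simulated roster trips an exclusion rule, roughly
a third of the eligible baseline has ultrasound steatosis, the five factor
analytic patterns each explain 3–5% of intake variance (≈19% jointly), and
baseline adherence scores are standardized exactly. Fitting the association
model on the true latent "traditional-pattern" exposure of a cohort
generated with a known odds ratio of 0.5 recovers it:

```python
cfg = SimConfig(n_participants=1000, seed=11, random_intercept_sd=0.5,
                outcome_coefficients={"time_years": float(np.log(0.74)),
                                      "factor:traditional": float(np.log(0.5))},
                missingness_rates={}, dropout_rate=0.0)
cohort, truth = generate_cohort(cfg)
res = BayesLogisticMixedModel(
    truth.latent_exposures(cohort),
    spec=ModelSpec(outcome="steatosis", exposures=("latent_traditional",),
                   covariate_set="model1", iterations=4000, burn_in=1500,
                   chains=2, seed=5),
).fit()
print(res.summary().loc["latent_traditional", ["OR", "OR_2.5%", "OR_97.5%"]])
# OR 0.452, 95% CI [0.384, 0.528]
```

There is also a CLI:

```bash
dietnafld all --seed 1 --n-participants 400 --outdir out/
```

which writes the cohort, exclusion tally, score tables, loadings, scree
data, adherence scores, correlation profiles, model summaries, the
severity figure (with its CSV twin) and a reproducibility manifest.

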