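"""Bayesian mixed models: GLM collapse, imputation, pooling, screens."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dietnafld.bayes import (
    BayesLinearMixedModel,
    BayesLogisticMixedModel,
    ModelSpec,
    PosteriorSummary,
    extract_imputations,
    fit_bmi_lmm,
    pool_fits,
    screen_interactions,
    univariable_foodgroup_screen,
)
from dietnafld.simulate import SimConfig, generate_cohort


def _two_visit_frame(n, beta0, beta1, tau, seed, outcome="steatosis"):
    rng = np.random.default_rng(seed)
    pid = np.repeat(np.arange(n), 2)
    x = 0.7 * np.repeat(rng.standard_normal(n), 2) + 0.3 * rng.standard_normal(2 * n)
    b = np.repeat(rng.normal(0, tau, n), 2) if tau > 0 else 0.0
    lp = beta0 + beta1 * x + b
    y = (rng.random(2 * n) < 1 / (1 + np.exp(-lp))).astype(int)
    return pd.DataFrame({"participant_id": pid, "visit": np.tile([1, 2], n),
                         outcome: y, "diet": x})


@pytest.fixture(scope="module")
def glm_collapse_fit():
    df = _two_visit_frame(400, -0.5, 0.8, tau=0.0, seed=0)
    spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="none",
                     iterations=4000, burn_in=1500, chains=2, seed=1)
    res = BayesLogisticMixedModel(df, spec=spec).fit()
    glm = sm.Logit(df["steatosis"], sm.add_constant(df["diet"])).fit(disp=0)
    return res, glm


class TestCollapseToGLM:
    def test_fixed_effects_match_ordinary_logistic(self, glm_collapse_fit):
        res, glm = glm_collapse_fit
        assert res.table.loc["intercept", "mean"] == pytest.approx(glm.params.iloc[0], abs=0.2)
        assert res.table.loc["diet", "mean"] == pytest.approx(glm.params.iloc[1], abs=0.2)

    def test_intercept_sd_posterior_is_modest_when_truth_is_zero(self, glm_collapse_fit):
        res, _ = glm_collapse_fit
        assert res.table.loc["random_intercept_sd", "mean"] < 0.8

    def test_convergence_diagnostics_attached(self, glm_collapse_fit):
        res, _ = glm_collapse_fit
        assert (res.table["rhat"].dropna() < 1.1).all()
        assert (res.table["ess"].dropna() > 50).all()


class TestDeterminism:
    def test_same_seed_reproduces_chains_exactly(self):
        df = _two_visit_frame(120, -0.3, 0.5, tau=0.4, seed=3)
        spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="none",
                         iterations=600, burn_in=300, chains=1, seed=9)
        r1 = BayesLogisticMixedModel(df, spec=spec).fit()
        r2 = BayesLogisticMixedModel(df, spec=spec).fit()
        assert np.array_equal(r1.coef_chains, r2.coef_chains)


class TestScaleInvariance:
    def test_or_back_transformed_to_original_units(self):
        """Rescaling a covariate rescales its coefficient, leaving the per-unit OR consistent."""
        df = _two_visit_frame(300, -0.4, 0.6, tau=0.3, seed=4)
        spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="none",
                         iterations=3000, burn_in=1200, chains=1, seed=2)
        r1 = BayesLogisticMixedModel(df, spec=spec).fit()
        df2 = df.copy()
        df2["diet"] = df2["diet"] * 100.0
        r2 = BayesLogisticMixedModel(df2, spec=spec).fit()
        assert r2.table.loc["diet", "mean"] * 100 == pytest.approx(
            r1.table.loc["diet", "mean"], rel=0.15
        )


class TestGaussianFamily:
    def test_noiseless_fixture_recovered_near_exactly(self):
        rng = np.random.default_rng(5)
        n = 150
        pid = np.repeat(np.arange(n), 2)
        x = rng.standard_normal(2 * n)
        y = 2.0 + 1.5 * x + rng.normal(0, 1e-3, 2 * n)
        df = pd.DataFrame({"participant_id": pid, "visit": np.tile([1, 2], n),
                           "bmi": y, "diet": x})
        spec = ModelSpec(outcome="bmi", exposures=("diet",), covariate_set="none",
                         family="gaussian", iterations=2000, burn_in=800, chains=1, seed=6)
        res = BayesLinearMixedModel(df, spec=spec).fit()
        assert res.table.loc["intercept", "mean"] == pytest.approx(2.0, abs=0.02)
        assert res.table.loc["diet", "mean"] == pytest.approx(1.5, abs=0.02)

    def test_bmi_mediator_model_recovers_interaction_sign(self):
        rng = np.random.default_rng(7)
        cfg = SimConfig(n_participants=250, seed=30, missingness_rates={}, dropout_rate=0.0)
        cohort, truth = generate_cohort(cfg)
        cohort = truth.latent_exposures(cohort)
        # impose a positive diet x time effect on BMI
        cohort = cohort.copy()
        cohort["bmi"] = (
            26.0 + 0.5 * cohort["latent_traditional"] * cohort["time_years"]
            + rng.normal(0, 0.5, len(cohort))
        )
        res = fit_bmi_lmm(cohort, exposures=("latent_traditional",),
                          iterations=1500, burn_in=600, chains=1, seed=8)
        coef = res.table.loc["latent_traditional_x_time_years", "mean"]
        assert coef > 0.3
        assert "bmi" not in res.coef_names


class TestImputationMachinery:
    def test_no_missing_data_gives_identical_copies(self):
        df = _two_visit_frame(80, -0.3, 0.4, tau=0.3, seed=9)
        spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="none",
                         iterations=400, burn_in=200, chains=1, seed=3)
        res = BayesLogisticMixedModel(df, spec=spec).fit()
        sets = extract_imputations(res, df, m=5)
        assert len(sets) == 5
        for s in sets:
            pd.testing.assert_frame_equal(s, df)

    def test_m_exceeding_draws_errors(self):
        df = _two_visit_frame(50, 0.0, 0.0, tau=0.0, seed=10)
        spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="none",
                         iterations=210, burn_in=200, chains=1, seed=3)
        res = BayesLogisticMixedModel(df, spec=spec).fit()
        with pytest.raises(ValueError, match="exceeds"):
            extract_imputations(res, df, m=50)

    def test_missing_cells_filled_and_vary_across_sets(self, small_cohort):
        cohort, truth = small_cohort
        cohort = truth.latent_exposures(cohort)
        spec = ModelSpec(outcome="steatosis", exposures=("latent_traditional",),
                         covariate_set="model2", iterations=900, burn_in=400,
                         chains=1, seed=4)
        res = BayesLogisticMixedModel(cohort, spec=spec).fit()
        assert len(res.missing_index) > 0
        sets = extract_imputations(res, cohort, m=10)
        for s in sets:
            assert not s["education"].isna().any()
            assert not s["physical_activity"].isna().any()
        first, last = sets[0], sets[-1]
        assert (first["physical_activity"] != last["physical_activity"]).any()

    def test_outcome_with_missing_values_rejected(self):
        df = _two_visit_frame(30, 0.0, 0.0, tau=0.0, seed=11)
        df.loc[0, "steatosis"] = np.nan
        with pytest.raises(ValueError, match="outcome"):
            BayesLogisticMixedModel(
                df, spec=ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="none")
            )


class TestPooling:
    def test_pooling_identical_fits_equals_single_fit(self):
        df = _two_visit_frame(100, -0.3, 0.5, tau=0.3, seed=12)
        spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="none",
                         iterations=600, burn_in=300, chains=1, seed=5)
        res = BayesLogisticMixedModel(df, spec=spec).fit()
        pooled = pool_fits([res, res])
        assert pooled.table["mean"].equals(res.table["mean"])

    def test_disjoint_support_mixture_spans_both_components(self):
        def fake(center):
            chains = np.full((1, 200, 1), float(center))
            chains += np.linspace(-0.01, 0.01, 200)[None, :, None]
            table = pd.DataFrame({"mean": [center]}, index=["diet"])
            return PosteriorSummary(
                table=table, coef_chains=chains, coef_names=["diet"],
                tau_chains=np.ones((1, 200)), missing_chains=None,
                missing_index=[], family="logistic", converged=True,
            )

        pooled = pool_fits([fake(0.0), fake(10.0)])
        assert pooled.table.loc["diet", "ci_2.5%"] < 0.1
        assert pooled.table.loc["diet", "ci_97.5%"] > 9.9

    def test_structure_mismatch_rejected(self):
        df = _two_visit_frame(60, 0.0, 0.0, tau=0.0, seed=13)
        spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="none",
                         iterations=400, burn_in=200, chains=1, seed=6)
        res = BayesLogisticMixedModel(df, spec=spec).fit()
        other = PosteriorSummary(
            table=res.table, coef_chains=res.coef_chains, coef_names=["something_else"],
            tau_chains=res.tau_chains, missing_chains=None, missing_index=[],
            family="logistic", converged=True,
        )
        with pytest.raises(ValueError, match="structure"):
            pool_fits([res, other])


class TestInteractionScreen:
    def test_null_interaction_judged_not_relevant(self):
        rng = np.random.default_rng(14)
        n = 250
        pid = np.repeat(np.arange(n), 2)
        time = np.tile([0.0, 4.4], n)
        x = rng.standard_normal(2 * n)
        lp = -0.5 + 0.5 * x - 0.2 * time  # no interaction in truth
        y = (rng.random(2 * n) < 1 / (1 + np.exp(-lp))).astype(int)
        df = pd.DataFrame({"participant_id": pid, "visit": np.tile([1, 2], n),
                           "time_years": time, "steatosis": y, "diet": x,
                           "sex": "female", "age": 70.0,
                           "education": "low", "physical_activity": 40.0,
                           "energy_kcal": 2000.0, "alcohol_units": 0.5})
        spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="model1",
                         interactions=("diet_x_time",), iterations=1500, burn_in=600,
                         chains=1, seed=7)
        decision, refit = screen_interactions(df, spec)
        assert not decision["relevant"].iloc[0]
        assert not any("_x_" in c for c in refit.coef_names)

    def test_strong_interaction_judged_relevant(self):
        rng = np.random.default_rng(15)
        n = 400
        pid = np.repeat(np.arange(n), 2)
        time = np.tile([0.0, 4.4], n)
        x = rng.standard_normal(2 * n)
        lp = -0.3 + 0.1 * x - 0.5 * x * time
        y = (rng.random(2 * n) < 1 / (1 + np.exp(-lp))).astype(int)
        df = pd.DataFrame({"participant_id": pid, "visit": np.tile([1, 2], n),
                           "time_years": time, "steatosis": y, "diet": x,
                           "sex": "male", "age": 70.0,
                           "education": "low", "physical_activity": 40.0,
                           "energy_kcal": 2000.0, "alcohol_units": 0.5})
        spec = ModelSpec(outcome="steatosis", exposures=("diet",), covariate_set="model1",
                         interactions=("diet_x_time",), iterations=2000, burn_in=800,
                         chains=1, seed=8)
        decision, _ = screen_interactions(df, spec)
        assert decision["relevant"].iloc[0]

    def test_bmi_interaction_requires_model2(self):
        with pytest.raises(ValueError, match="model2"):
            ModelSpec(exposures=("diet",), covariate_set="model1",
                      interactions=("diet_x_bmi",))


class TestUnivariableScreen:
    def test_known_effect_recovered_and_null_is_flat(self):
        rng = np.random.default_rng(16)
        cfg = SimConfig(n_participants=5000, seed=40, missingness_rates={}, dropout_rate=1.0,
                        n_visits=1)
        cohort, _ = generate_cohort(cfg)
        base = cohort[cohort["visit"] == 1].copy()
        z = (base["vegetables"] - base["vegetables"].mean()) / base["vegetables"].std()
        lp = -0.6 + np.log(1.6) * z
        base["steatosis"] = (rng.random(len(base)) < 1 / (1 + np.exp(-lp))).astype(int)
        table = univariable_foodgroup_screen(base)
        assert table.loc["vegetables", "or_per_sd"] == pytest.approx(1.6, abs=0.15)
        # an unrelated group stays near the null
        assert table.loc["coffee", "or_per_sd"] == pytest.approx(1.0, abs=0.1)

    def test_unit_rescaling_leaves_or_unchanged(self, small_cohort):
        cohort, _ = small_cohort
        base = cohort[cohort["visit"] == 1].copy()
        t1 = univariable_foodgroup_screen(base)
        base2 = base.copy()
        base2["fruit"] = base2["fruit"] * 2.0
        t2 = univariable_foodgroup_screen(base2)
        assert t2.loc["fruit", "or_per_sd"] == pytest.approx(t1.loc["fruit", "or_per_sd"], rel=1e-6)

    def test_degenerate_group_flagged_and_skipped(self, small_cohort):
        cohort, _ = small_cohort
        base = cohort[cohort["visit"] == 1].copy()
        base["soy_products"] = 0.0
        table = univariable_foodgroup_screen(base)
        assert table.loc["soy_products", "degenerate"]
        assert np.isnan(table.loc["soy_products", "or_per_sd"])
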