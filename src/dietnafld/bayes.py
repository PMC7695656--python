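"""Bayesian mixed-effects association models with covariate imputation.

Longitudinal association between dietary-pattern adherence and hepatic
steatosis is modelled with a random-intercept logistic regression

    y_ij ~ Bernoulli(expit(x_ij' beta + b_i)),   b_i ~ N(0, tau^2),

fitted by MCMC (adaptive Metropolis-within-Gibbs). Missing covariate values
are treated as unknowns and sampled jointly with the coefficients: each
incomplete covariate gets a conditional model (continuous -> linear, binary
-> logistic, ordered categorical -> cumulative logit) in a sequential
factorization whose predictors are the complete covariates of the most
extensive covariate set, so coefficient uncertainty automatically reflects
the missing data. A Gaussian-outcome variant of the same machinery serves
the BMI mediator analyses.

Priors are non-informative by default: N(0, 10^2) on coefficients of
internally standardized covariates, half-normal(2.5) on the random-intercept
SD. Coefficients are reported back on the original covariate scale
(odds ratios per unit for the logistic model).

Two covariate sets mirror the confounder strategy of the emulated study:
"model1" = sex, baseline age, baseline education, baseline physical
activity, energy intake, alcohol intake, follow-up time; "model2"
additionally BMI, baseline diabetes, baseline hypertension. Diet exposures
enter time-varying; covariates marked baseline are carried forward.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

MODEL1_COVARIATES = (
    "female", "age", "education", "physical_activity",
    "energy_kcal", "alcohol_units", "time_years",
)
MODEL2_EXTRA = ("bmi", "diabetes", "hypertension")

_EDU_LEVELS = ("low", "intermediate", "high")


@dataclass
class ModelSpec:
    """What to fit: outcome, exposures, covariate set, interactions, MCMC settings."""

    outcome: str = "steatosis"
    exposures: tuple[str, ...] = ()
    covariate_set: str = "model1"  # "model1" | "model2" | "none"
    interactions: tuple[str, ...] = ()  # subset of {"diet_x_time", "diet_x_bmi"}
    family: str = "logistic"  # "logistic" | "gaussian"
    chains: int = 2
    iterations: int = 2500
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    beta_prior_sd: float = 10.0
    tau_prior_scale: float = 2.5

    def __post_init__(self):
        if self.covariate_set not in ("model1", "model2", "none"):
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")
        bad = set(self.interactions) - {"diet_x_time", "diet_x_bmi"}
        if bad:
            raise ValueError(f"unknown interactions: {sorted(bad)}")
        if "diet_x_bmi" in self.interactions and self.covariate_set != "model2":
            raise ValueError("diet_x_bmi interaction requires the model2 covariate set")
        if self.family not in ("logistic", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ImputationSpec:
    """Conditional model family per incomplete covariate.

    ``families`` maps covariate name -> "normal" | "logistic" | "cumlogit".
    Unlisted incomplete covariates get a family inferred from their values
    (binary -> logistic, ordered categorical -> cumlogit, else normal).
    Predictors are the complete covariates of the model-2 set plus
    previously factorized incomplete covariates (sequential factorization,
    acyclic by construction). The outcome and the exposures are never
    imputed.
    """

    families: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# internal data preparation


def _carry_forward_baseline(data: pd.DataFrame, id_col: str) -> pd.DataFrame:
    """Carry baseline values of baseline-only covariates to follow-up rows."""
    df = data.copy().sort_values([id_col, "visit"] if "visit" in data.columns else [id_col])
    baseline_cols = [c for c in ("age", "education", "physical_activity", "diabetes", "hypertension", "sex") if c in df.columns]
    base = df.groupby(id_col, sort=False).first()
    for c in baseline_cols:
        df[c] = base.loc[df[id_col], c].to_numpy()
    return df.reset_index(drop=True)


def _education_numeric(series: pd.Series) -> np.ndarray:
    vals = np.full(len(series), np.nan)
    arr = series.to_numpy(object)
    for i, v in enumerate(arr):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if isinstance(v, str):
            vals[i] = float(_EDU_LEVELS.index(v))
        else:
            vals[i] = float(v)
    return vals


class _Column:
    """One design column: raw values, standardization, current state."""

    def __init__(self, name: str, values: np.ndarray, standardize: bool):
        self.name = name
        self.raw = np.asarray(values, float)
        finite = self.raw[~np.isnan(self.raw)]
        if standardize and len(finite) and np.nanstd(self.raw) > 0:
            self.mu = float(np.nanmean(self.raw))
            self.sd = float(np.nanstd(self.raw))
        else:
            self.mu, self.sd = 0.0, 1.0

    def std(self, values: np.ndarray | None = None) -> np.ndarray:
        v = self.raw if values is None else values
        return (v - self.mu) / self.sd


# ---------------------------------------------------------------------------
# results object


@dataclass
class PosteriorSummary:
    """Posterior summary table plus retained chains."""

    table: pd.DataFrame           # per coefficient: mean, OR, CI, tail prob, ess, rhat
    coef_chains: np.ndarray       # (chains, draws, p) on the original covariate scale
    coef_names: list[str]
    tau_chains: np.ndarray | None  # (chains, draws)
    missing_chains: np.ndarray | None  # (chains, draws, n_missing)
    missing_index: list[tuple[str, int]]  # (covariate, participant position)
    family: str
    converged: bool
    spec: ModelSpec | None = None
    sigma_chains: np.ndarray | None = None  # gaussian residual SD

    def summary(self) -> pd.DataFrame:
        return self.table

    def coef(self, name: str) -> np.ndarray:
        j = self.coef_names.index(name)
        return self.coef_chains[:, :, j].ravel()


def _tail_probability(draws: np.ndarray) -> float:
    p_pos = float(np.mean(draws > 0))
    p = 2 * min(p_pos, 1 - p_pos)
    return max(p, 1.0 / draws.size)


def _summarize(
    coef_chains: np.ndarray,
    names: list[str],
    family: str,
    tau_chains: np.ndarray | None,
    sigma_chains: np.ndarray | None = None,
) -> tuple[pd.DataFrame, bool]:
    import arviz as az

    rows = []
    rhats = []
    for j, name in enumerate(names):
        d = coef_chains[:, :, j]
        flat = d.ravel()
        mean = float(flat.mean())
        lo, hi = np.percentile(flat, [2.5, 97.5])
        ds = az.convert_to_dataset(d[:, :, None], group="posterior")
        rhat = float(np.asarray(az.rhat(ds).x.values).ravel()[0])
        ess = float(np.asarray(az.ess(ds).x.values).ravel()[0])
        rhats.append(rhat)
        row = {
            "coef": name,
            "mean": mean,
            "ci_2.5%": float(lo),
            "ci_97.5%": float(hi),
            "tail_prob": _tail_probability(flat),
            "ess": ess,
            "rhat": rhat,
        }
        if family == "logistic":
            row["OR"] = float(np.exp(mean))
            row["OR_2.5%"] = float(np.exp(lo))
            row["OR_97.5%"] = float(np.exp(hi))
        rows.append(row)
    extra = []
    if tau_chains is not None:
        flat = tau_chains.ravel()
        extra.append({
            "coef": "random_intercept_sd",
            "mean": float(flat.mean()),
            "ci_2.5%": float(np.percentile(flat, 2.5)),
            "ci_97.5%": float(np.percentile(flat, 97.5)),
            "tail_prob": np.nan, "ess": np.nan, "rhat": np.nan,
        })
    if sigma_chains is not None:
        flat = sigma_chains.ravel()
        extra.append({
            "coef": "residual_sd",
            "mean": float(flat.mean()),
            "ci_2.5%": float(np.percentile(flat, 2.5)),
            "ci_97.5%": float(np.percentile(flat, 97.5)),
            "tail_prob": np.nan, "ess": np.nan, "rhat": np.nan,
        })
    table = pd.DataFrame(rows + extra).set_index("coef")
    converged = bool(np.all(np.asarray(rhats) < 1.1))
    return table, converged


# ---------------------------------------------------------------------------
# the model


class BayesMixedModel:
    """Random-intercept Bayesian regression with simultaneous imputation.

    Parameters
    ----------
    data
        Participant-visit table (long format).
    spec
        :class:`ModelSpec`; ``spec.family`` selects logistic (binary
        outcome) or gaussian (continuous outcome).
    imputation
        :class:`ImputationSpec`; families for incomplete covariates.
    id_col
        Participant identifier column.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: ModelSpec,
        imputation: ImputationSpec | None = None,
        id_col: str = "participant_id",
    ):
        self.spec = spec
        self.imputation = imputation or ImputationSpec()
        self.id_col = id_col
        df = _carry_forward_baseline(data, id_col)

        y = df[spec.outcome].to_numpy(float)
        if np.isnan(y).any():
            raise ValueError(f"outcome {spec.outcome!r} contains missing values; outcomes are never imputed")
        for e in spec.exposures:
            if df[e].isna().any():
                raise ValueError(f"exposure {e!r} contains missing values; exposures are never imputed")
        self.y = y
        pid, self.pid_index = np.unique(df[id_col].to_numpy(), return_inverse=True)
        self.n_participants = len(pid)
        self.n_rows = len(df)
        self.df = df

        covs = []
        if spec.covariate_set in ("model1", "model2"):
            covs += list(MODEL1_COVARIATES)
        if spec.covariate_set == "model2":
            covs += list(MODEL2_EXTRA)
        self.covariates = covs

        # raw covariate values at row level
        raw: dict[str, np.ndarray] = {}
        for c in covs:
            if c == "female":
                raw[c] = (df["sex"].astype(str).str.lower().isin(["female", "f"])).to_numpy(float)
            elif c == "education":
                raw[c] = _education_numeric(df["education"])
            else:
                raw[c] = df[c].to_numpy(float)
        for e in spec.exposures:
            raw[e] = df[e].to_numpy(float)
        self.raw = raw

        # incomplete covariates (participant-level, ordered by rising missingness)
        self.incomplete: list[str] = []
        for c in covs:
            if np.isnan(raw[c]).any():
                self.incomplete.append(c)
        base_rows = ~df.duplicated(id_col).to_numpy()
        self.base_rows = base_rows
        self.incomplete.sort(key=lambda c: np.isnan(raw[c][base_rows]).sum())
        self.families = {}
        for c in self.incomplete:
            fam = self.imputation.families.get(c)
            if fam is None:
                obs = raw[c][~np.isnan(raw[c])]
                uniq = np.unique(obs)
                if set(uniq) <= {0.0, 1.0}:
                    fam = "logistic"
                elif c == "education" or (len(uniq) <= 4 and np.allclose(uniq, np.round(uniq))):
                    fam = "cumlogit"
                else:
                    fam = "normal"
            if fam not in ("normal", "logistic", "cumlogit"):
                raise ValueError(f"unknown imputation family {fam!r} for {c!r}")
            self.families[c] = fam

        self._build_design()

    # -- design ------------------------------------------------------------

    def _build_design(self):
        spec = self.spec
        self.columns: list[str] = ["intercept"]
        parts: dict[str, _Column] = {}
        binary = {"female", "diabetes", "hypertension"}
        for e in spec.exposures:
            parts[e] = _Column(e, self.raw[e], standardize=True)
            self.columns.append(e)
        for c in self.covariates:
            if c == "education":
                edu = self.raw["education"]
                parts["education_intermediate"] = _Column("education_intermediate", (edu == 1).astype(float), False)
                parts["education_high"] = _Column("education_high", (edu == 2).astype(float), False)
                self.columns += ["education_intermediate", "education_high"]
            else:
                parts[c] = _Column(c, self.raw[c], standardize=c not in binary)
                self.columns.append(c)
        for inter in spec.interactions:
            other = "time_years" if inter == "diet_x_time" else "bmi"
            for e in spec.exposures:
                name = f"{e}_x_{other}"
                parts[name] = _Column(name, self.raw[e] * self.raw[other], standardize=True)
                self.columns.append(name)
        self._parts = parts
        self._interaction_names = [c for c in self.columns if "_x_" in c]

        # initial fill for incomplete covariates (participant-level value)
        self.mis_index: list[tuple[str, int]] = []
        self.current: dict[str, np.ndarray] = {}
        for c in self.incomplete:
            v = self.raw[c].copy()
            base_vals = v[self.base_rows]
            obs = base_vals[~np.isnan(base_vals)]
            fill = float(np.round(np.median(obs))) if self.families[c] != "normal" else float(obs.mean())
            pvals = np.full(self.n_participants, np.nan)
            pvals[self.pid_index[~np.isnan(v)]] = v[~np.isnan(v)]
            # only participants with no observed value anywhere are latent
            miss_pids = np.where(np.isnan(pvals))[0]
            pvals[miss_pids] = fill
            self.current[c] = pvals
            self.mis_index += [(c, int(p)) for p in miss_pids]

        self.X = np.empty((self.n_rows, len(self.columns)))
        self._refresh_X()

    def _refresh_X(self, only: str | None = None):
        for j, name in enumerate(self.columns):
            if name == "intercept":
                self.X[:, j] = 1.0
                continue
            col = self._parts[name]
            base = name.split("_x_")[0] if "_x_" in name else name
            if only is not None and base != only and not name.startswith("education"):
                continue
            if name in ("education_intermediate", "education_high") and "education" in self.incomplete:
                if only is not None and only != "education":
                    continue
                edu = self.current["education"][self.pid_index]
                level = 1.0 if name.endswith("intermediate") else 2.0
                self.X[:, j] = (edu == level).astype(float)
            elif base in self.incomplete:
                vals = self.current[base][self.pid_index]
                if "_x_" in name:
                    other = self.raw["time_years"] if name.endswith("time_years") else self.raw["bmi"]
                    vals = vals * other
                self.X[:, j] = col.std(vals)
            else:
                self.X[:, j] = col.std()

    # -- covariate (imputation) models ------------------------------------

    def _participant_predictors(self, upto: str) -> np.ndarray:
        """Predictor matrix for a covariate model: intercept + complete model-2
        covariates + incomplete covariates earlier in the factorization."""
        cols = [np.ones(self.n_participants)]
        pos = {p: i for i, p in enumerate(self.incomplete)}
        first = self.base_rows
        for c in self.covariates:
            if c == upto:
                continue
            if c in self.incomplete:
                if pos[c] < pos[upto]:
                    cols.append(self.current[c])
                continue
            v = self.raw[c][first]
            sd = v.std() if v.std() > 0 else 1.0
            cols.append((v - v.mean()) / sd)
        return np.column_stack(cols)

    # -- likelihood pieces -------------------------------------------------

    def _row_loglik(self, lp: np.ndarray, extra: dict | None = None) -> np.ndarray:
        if self.spec.family == "logistic":
            return self.y * lp - np.logaddexp(0.0, lp)
        sigma = extra["sigma"]
        return -0.5 * ((self.y - lp) / sigma) ** 2 - np.log(sigma)

    # -- the sampler -------------------------------------------------------

    def fit(self) -> PosteriorSummary:
        spec = self.spec
        keep = (spec.iterations - spec.burn_in) // spec.thin
        if keep < 2:
            raise ValueError("iterations/burn_in leave no draws to keep")
        p = len(self.columns)
        coef_chains = np.empty((spec.chains, keep, p))
        tau_chains = np.empty((spec.chains, keep))
        sigma_chains = np.empty((spec.chains, keep)) if spec.family == "gaussian" else None
        nmis = len(self.mis_index)
        mis_chains = np.empty((spec.chains, keep, nmis)) if nmis else None

        for chain in range(spec.chains):
            rng = np.random.default_rng((spec.seed * 1000003 + chain * 7919) % (2**31))
            state = self._init_state(rng)
            kept = 0
            for it in range(spec.iterations):
                adapting = it < spec.burn_in
                self._update_beta(state, rng, adapting, it)
                self._update_intercepts(state, rng, adapting)
                self._update_recenter(state, rng, adapting)
                self._update_centered_covariates(state, rng, adapting)
                self._update_tau(state, rng, adapting)
                if spec.family == "gaussian":
                    self._update_sigma(state, rng)
                if nmis:
                    self._update_covariate_models(state, rng, adapting)
                    self._update_missing(state, rng, adapting)
                if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and kept < keep:
                    coef_chains[chain, kept] = self._to_original_scale(state["beta"])
                    tau_chains[chain, kept] = state["tau"]
                    if sigma_chains is not None:
                        sigma_chains[chain, kept] = state["sigma"]
                    if mis_chains is not None:
                        mis_chains[chain, kept] = np.array(
                            [self.current[c][pp] for c, pp in self.mis_index]
                        )
                    kept += 1

        table, converged = _summarize(
            coef_chains, self._original_names(), spec.family,
            tau_chains, sigma_chains,
        )
        return PosteriorSummary(
            table=table,
            coef_chains=coef_chains,
            coef_names=self._original_names(),
            tau_chains=tau_chains,
            missing_chains=mis_chains,
            missing_index=list(self.mis_index),
            family=spec.family,
            converged=converged,
            spec=spec,
            sigma_chains=sigma_chains,
        )

    def _original_names(self) -> list[str]:
        return list(self.columns)

    def _to_original_scale(self, beta_std: np.ndarray) -> np.ndarray:
        out = beta_std.copy()
        shift = 0.0
        for j, name in enumerate(self.columns):
            if name == "intercept":
                continue
            col = self._parts[name]
            out[j] = beta_std[j] / col.sd
            shift += beta_std[j] * col.mu / col.sd
        out[self.columns.index("intercept")] = beta_std[self.columns.index("intercept")] - shift
        return out

    def _init_state(self, rng: np.random.Generator) -> dict:
        p = len(self.columns)
        state = {
            "beta": np.zeros(p),
            "b": np.zeros(self.n_participants),
            "tau": 0.5,
            "sigma": float(np.std(self.y)) if self.spec.family == "gaussian" else None,
            "beta_scale": 0.2 / np.sqrt(p),
            "beta_cw_scale": np.full(p, 0.15),
            "beta_ctr_scale": np.full(p, 0.3),
            "beta_mean": np.zeros(p),
            "beta_cov": np.eye(p),
            "beta_count": 0,
            "b_scale": 0.8,
            "tau_scale": 0.3,
            "cov_params": {},
            "mis_scale": {c: 0.5 for c in self.incomplete},
            "covp_scale": {},
        }
        if self.spec.family == "gaussian":
            # crude OLS start helps short chains
            beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
            state["beta"] = beta
        for c in self.incomplete:
            W = self._participant_predictors(c)
            q = W.shape[1]
            if self.families[c] == "normal":
                state["cov_params"][c] = {"theta": np.zeros(q), "sigma2": 1.0}
            elif self.families[c] == "logistic":
                state["cov_params"][c] = {"theta": np.zeros(q)}
                state["covp_scale"][c] = 0.1
            else:
                state["cov_params"][c] = {"theta": np.zeros(q - 1), "alpha": np.array([-0.5, 0.5])}
                state["covp_scale"][c] = 0.1
        state["lp"] = self.X @ state["beta"] + state["b"][self.pid_index]
        return state

    # individual updates ---------------------------------------------------

    def _loglik_total(self, lp: np.ndarray, state: dict) -> float:
        return float(self._row_loglik(lp, state).sum())

    def _update_beta(self, state, rng, adapting, it):
        p = len(self.columns)
        beta = state["beta"]
        if state["beta_count"] > 2 * p:
            cov = state["beta_cov"] + 1e-9 * np.eye(p)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                chol = np.eye(p)
            prop = beta + state["beta_scale"] * (chol @ rng.standard_normal(p))
        else:
            prop = beta + state["beta_scale"] * rng.standard_normal(p)
        lp_new = self.X @ prop + state["b"][self.pid_index]
        prior = -0.5 * (prop @ prop - beta @ beta) / self.spec.beta_prior_sd**2
        delta = self._loglik_total(lp_new, state) - self._loglik_total(state["lp"], state) + prior
        accept = np.log(rng.random()) < delta
        if accept:
            state["beta"] = prop
            state["lp"] = lp_new
        # componentwise sweep with per-coordinate adapted scales: the joint
        # move handles correlated directions, the sweep fixes per-axis scale
        scales = state["beta_cw_scale"]
        beta = state["beta"]
        lp = state["lp"]
        ll_rows = self._row_loglik(lp, state)
        for j in rng.permutation(p):
            step = scales[j] * rng.standard_normal()
            lp_new = lp + step * self.X[:, j]
            ll_new = self._row_loglik(lp_new, state)
            dprior = -0.5 * ((beta[j] + step) ** 2 - beta[j] ** 2) / self.spec.beta_prior_sd**2
            acc_j = np.log(rng.random()) < ll_new.sum() - ll_rows.sum() + dprior
            if acc_j:
                beta[j] += step
                lp = lp_new
                ll_rows = ll_new
            if adapting:
                scales[j] *= np.exp(0.25 * ((1.0 if acc_j else 0.0) - 0.44))
        state["beta"] = beta
        state["lp"] = lp
        if adapting:
            state["beta_scale"] *= np.exp(0.6 * ((1.0 if accept else 0.0) - 0.234) / (1 + it) ** 0.4)
            n = state["beta_count"]
            mean = state["beta_mean"]
            new_mean = mean + (state["beta"] - mean) / (n + 1)
            state["beta_cov"] = (
                state["beta_cov"] * (n / (n + 1))
                + np.outer(state["beta"] - mean, state["beta"] - new_mean) / (n + 1)
            ) if n > 0 else np.eye(p) * 0.01
            state["beta_mean"] = new_mean
            state["beta_count"] = n + 1

    def _update_intercepts(self, state, rng, adapting):
        b = state["b"]
        prop = b + state["b_scale"] * rng.standard_normal(self.n_participants)
        lp_new = state["lp"] + (prop - b)[self.pid_index]
        dll_rows = self._row_loglik(lp_new, state) - self._row_loglik(state["lp"], state)
        dll = np.bincount(self.pid_index, weights=dll_rows, minlength=self.n_participants)
        tau2 = max(state["tau"] ** 2, 1e-12)
        dprior = -0.5 * (prop**2 - b**2) / tau2
        accept = np.log(rng.random(self.n_participants)) < dll + dprior
        b_new = np.where(accept, prop, b)
        state["lp"] = state["lp"] + (b_new - b)[self.pid_index]
        state["b"] = b_new
        if adapting:
            rate = accept.mean()
            state["b_scale"] *= np.exp(0.3 * (rate - 0.44))

    def _update_centered_covariates(self, state, rng, adapting):
        # joint (beta_j, b) moves along the participant-mean direction of each
        # column: only within-participant deviations inform the likelihood
        # delta, so these directions accept large steps that plain
        # componentwise moves cannot make
        counts = np.bincount(self.pid_index, minlength=self.n_participants).astype(float)
        scales = state["beta_ctr_scale"]
        tau2 = max(state["tau"] ** 2, 1e-12)
        ll_cur = self._row_loglik(state["lp"], state).sum()
        for j, name in enumerate(self.columns):
            if name == "intercept":
                continue
            m = np.bincount(self.pid_index, weights=self.X[:, j], minlength=self.n_participants) / counts
            delta = scales[j] * rng.standard_normal()
            lp_new = state["lp"] + delta * (self.X[:, j] - m[self.pid_index])
            b_new = state["b"] - delta * m
            ll_new = self._row_loglik(lp_new, state).sum()
            dll = ll_new - ll_cur
            dprior_b = -0.5 * (b_new @ b_new - state["b"] @ state["b"]) / tau2
            bj = state["beta"][j]
            dprior_beta = -0.5 * ((bj + delta) ** 2 - bj**2) / self.spec.beta_prior_sd**2
            acc = np.log(rng.random()) < dll + dprior_b + dprior_beta
            if acc:
                state["beta"][j] += delta
                state["b"] = b_new
                state["lp"] = lp_new
                ll_cur = ll_new
            if adapting:
                scales[j] *= np.exp(0.25 * ((1.0 if acc else 0.0) - 0.44))

    def _update_recenter(self, state, rng, adapting):
        # joint shift beta0 + delta, b - delta: likelihood-invariant move that
        # decouples the intercept from the random-effect block
        j0 = self.columns.index("intercept")
        delta = state.get("rc_scale", 0.2) * rng.standard_normal()
        b = state["b"]
        tau2 = max(state["tau"] ** 2, 1e-12)
        dprior_b = -0.5 * (np.sum((b - delta) ** 2) - np.sum(b**2)) / tau2
        beta0 = state["beta"][j0]
        dprior_beta = -0.5 * ((beta0 + delta) ** 2 - beta0**2) / self.spec.beta_prior_sd**2
        accept = np.log(rng.random()) < dprior_b + dprior_beta
        if accept:
            state["beta"][j0] += delta
            state["b"] = b - delta
        if adapting:
            state["rc_scale"] = state.get("rc_scale", 0.2) * np.exp(
                0.3 * ((1.0 if accept else 0.0) - 0.44)
            )

    def _update_tau(self, state, rng, adapting):
        tau = state["tau"]
        log_prop = np.log(tau) + state["tau_scale"] * rng.standard_normal()
        prop = float(np.exp(log_prop))
        b = state["b"]
        n = self.n_participants

        def logpost(t):
            # half-normal prior, log-scale Jacobian
            return (
                -n * np.log(t)
                - 0.5 * (b @ b) / t**2
                - 0.5 * t**2 / self.spec.tau_prior_scale**2
                + np.log(t)
            )

        accept = np.log(rng.random()) < logpost(prop) - logpost(tau)
        if accept:
            state["tau"] = prop
        if adapting:
            state["tau_scale"] *= np.exp(0.3 * ((1.0 if accept else 0.0) - 0.44))

    def _update_sigma(self, state, rng):
        resid = self.y - state["lp"]
        a = 0.01 + self.n_rows / 2
        bscale = 0.01 + 0.5 * resid @ resid
        state["sigma"] = float(np.sqrt(bscale / rng.gamma(a)))

    # covariate-model parameter updates

    def _covmodel_loglik(self, c: str, theta, alpha=None, sigma2=None, values=None) -> np.ndarray:
        W = self._participant_predictors(c)
        v = self.current[c] if values is None else values
        fam = self.families[c]
        eta = W @ theta if fam != "cumlogit" else W[:, 1:] @ theta
        if fam == "normal":
            return -0.5 * (v - eta) ** 2 / sigma2 - 0.5 * np.log(sigma2)
        if fam == "logistic":
            return v * eta - np.logaddexp(0.0, eta)
        # cumulative logit, categories 0..K with cutpoints alpha (ordered)
        K = len(alpha)
        cum = np.empty((self.n_participants, K + 2))
        cum[:, 0] = 0.0
        cum[:, -1] = 1.0
        for j, a in enumerate(alpha):
            cum[:, j + 1] = special.expit(a - eta)
        cum[:, 1:-1] = np.maximum.accumulate(cum[:, 1:-1], axis=1)
        idx = v.astype(int)
        probs = cum[np.arange(self.n_participants), idx + 1] - cum[np.arange(self.n_participants), idx]
        return np.log(np.clip(probs, 1e-300, None))

    def _update_covariate_models(self, state, rng, adapting):
        for c in self.incomplete:
            fam = self.families[c]
            params = state["cov_params"][c]
            W = self._participant_predictors(c)
            v = self.current[c]
            if fam == "normal":
                sigma2 = params["sigma2"]
                prec = W.T @ W / sigma2 + np.eye(W.shape[1]) / 100.0
                chol = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, W.T @ v / sigma2)
                params["theta"] = mean + np.linalg.solve(chol.T, rng.standard_normal(W.shape[1]))
                resid = v - W @ params["theta"]
                params["sigma2"] = float(
                    (0.01 + 0.5 * resid @ resid) / rng.gamma(0.01 + len(v) / 2)
                )
            elif fam == "logistic":
                theta = params["theta"]
                prop = theta + state["covp_scale"][c] * rng.standard_normal(len(theta))
                d = (
                    self._covmodel_loglik(c, prop).sum()
                    - self._covmodel_loglik(c, theta).sum()
                    - 0.5 * (prop @ prop - theta @ theta) / 100.0
                )
                acc = np.log(rng.random()) < d
                if acc:
                    params["theta"] = prop
                if adapting:
                    state["covp_scale"][c] *= np.exp(0.3 * ((1.0 if acc else 0.0) - 0.234))
            else:  # cumlogit
                theta, alpha = params["theta"], params["alpha"]
                s = state["covp_scale"][c]
                prop_t = theta + s * rng.standard_normal(len(theta))
                prop_a = alpha + s * rng.standard_normal(len(alpha))
                if np.any(np.diff(prop_a) <= 0):
                    continue
                d = (
                    self._covmodel_loglik(c, prop_t, alpha=prop_a).sum()
                    - self._covmodel_loglik(c, theta, alpha=alpha).sum()
                    - 0.5 * (prop_t @ prop_t - theta @ theta) / 100.0
                    - 0.5 * (prop_a @ prop_a - alpha @ alpha) / 100.0
                )
                acc = np.log(rng.random()) < d
                if acc:
                    params["theta"], params["alpha"] = prop_t, prop_a
                if adapting:
                    state["covp_scale"][c] *= np.exp(0.3 * ((1.0 if acc else 0.0) - 0.234))

    def _update_missing(self, state, rng, adapting):
        for c in self.incomplete:
            fam = self.families[c]
            params = state["cov_params"][c]
            pmiss = np.array([pp for cc, pp in self.mis_index if cc == c], int)
            if len(pmiss) == 0:
                continue
            cur = self.current[c]
            if fam == "normal":
                prop_vals = cur.copy()
                prop_vals[pmiss] = cur[pmiss] + state["mis_scale"][c] * np.std(
                    cur
                ) * rng.standard_normal(len(pmiss))
            elif fam == "logistic":
                prop_vals = cur.copy()
                prop_vals[pmiss] = 1.0 - cur[pmiss]
            else:
                prop_vals = cur.copy()
                K = len(params["alpha"]) + 1
                shift = rng.integers(1, K, len(pmiss))
                prop_vals[pmiss] = (cur[pmiss] + shift) % K

            # covariate-model density difference (per participant)
            if fam == "normal":
                d_cov = self._covmodel_loglik(c, params["theta"], sigma2=params["sigma2"], values=prop_vals) - \
                        self._covmodel_loglik(c, params["theta"], sigma2=params["sigma2"], values=cur)
            elif fam == "logistic":
                d_cov = self._covmodel_loglik(c, params["theta"], values=prop_vals) - \
                        self._covmodel_loglik(c, params["theta"], values=cur)
            else:
                d_cov = self._covmodel_loglik(c, params["theta"], alpha=params["alpha"], values=prop_vals) - \
                        self._covmodel_loglik(c, params["theta"], alpha=params["alpha"], values=cur)

            # later covariate models in the factorization use c as a predictor
            pos = {p_: i for i, p_ in enumerate(self.incomplete)}
            d_later = np.zeros(self.n_participants)
            for c2 in self.incomplete:
                if pos[c2] <= pos[c]:
                    continue
                pr2 = state["cov_params"][c2]
                saved = self.current[c]
                self.current[c] = prop_vals
                ll_new = self._covmodel_loglik(c2, pr2["theta"], alpha=pr2.get("alpha"), sigma2=pr2.get("sigma2"))
                self.current[c] = saved
                ll_old = self._covmodel_loglik(c2, pr2["theta"], alpha=pr2.get("alpha"), sigma2=pr2.get("sigma2"))
                d_later += ll_new - ll_old

            # outcome-likelihood difference via the affected design columns
            lp_new = self._lp_with_values(state, c, prop_vals)
            dll_rows = self._row_loglik(lp_new, state) - self._row_loglik(state["lp"], state)
            d_out = np.bincount(self.pid_index, weights=dll_rows, minlength=self.n_participants)

            delta = d_cov + d_later + d_out
            accept_p = np.zeros(self.n_participants, bool)
            accept_p[pmiss] = np.log(rng.random(len(pmiss))) < delta[pmiss]
            if accept_p.any():
                new_vals = np.where(accept_p, prop_vals, cur)
                self.current[c] = new_vals
                self._refresh_X(only=c)
                state["lp"] = self.X @ state["beta"] + state["b"][self.pid_index]
            if adapting and fam == "normal":
                rate = accept_p[pmiss].mean()
                state["mis_scale"][c] *= np.exp(0.3 * (rate - 0.44))

    def _lp_with_values(self, state, c: str, prop_vals: np.ndarray) -> np.ndarray:
        """Linear predictor if covariate c took prop_vals (no mutation)."""
        saved = self.current[c]
        self.current[c] = prop_vals
        Xsave = self.X.copy()
        self._refresh_X(only=c)
        lp = self.X @ state["beta"] + state["b"][self.pid_index]
        self.X = Xsave
        self.current[c] = saved
        return lp


class BayesLogisticMixedModel(BayesMixedModel):
    """Random-intercept Bayesian logistic regression (binary outcome)."""

    def __init__(self, data, spec=None, imputation=None, id_col="participant_id", **kw):
        spec = spec or ModelSpec(**kw)
        if spec.family != "logistic":
            raise ValueError("use BayesLinearMixedModel for gaussian outcomes")
        super().__init__(data, spec, imputation, id_col)


class BayesLinearMixedModel(BayesMixedModel):
    """Random-intercept Bayesian linear regression (continuous outcome)."""

    def __init__(self, data, spec=None, imputation=None, id_col="participant_id", **kw):
        kw.setdefault("family", "gaussian")
        spec = spec or ModelSpec(**kw)
        if spec.family != "gaussian":
            raise ValueError("spec.family must be 'gaussian'")
        super().__init__(data, spec, imputation, id_col)


# ---------------------------------------------------------------------------
# spec-surface operations


def fit_logistic_mixed(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    imputation: ImputationSpec | None = None,
    strict: bool = False,
) -> PosteriorSummary:
    """Fit the random-intercept logistic model with simultaneous imputation."""
    model = BayesLogisticMixedModel(cohort, spec=spec, imputation=imputation)
    res = model.fit()
    if strict and not res.converged:
        raise RuntimeError("MCMC did not converge (Rhat >= 1.1); rerun with longer chains")
    return res


def extract_imputations(result: PosteriorSummary, cohort: pd.DataFrame, m: int = 10,
                        id_col: str = "participant_id") -> list[pd.DataFrame]:
    """Extract ``m`` completed datasets from equally spaced post-burn-in draws.

    With no missing data this returns ``m`` identical copies of the input.
    """
    n_draws = result.coef_chains.shape[0] * result.coef_chains.shape[1]
    if m > n_draws:
        raise ValueError(f"m={m} exceeds available post-burn-in draws ({n_draws})")
    datasets = []
    if result.missing_chains is None:
        return [cohort.copy() for _ in range(m)]
    # baseline-measured covariates observed at one visit are carried over
    carried = cohort.copy()
    for covariate in {c for c, _ in result.missing_index}:
        carried[covariate] = carried.groupby(id_col)[covariate].transform(
            lambda s: s.ffill().bfill()
        )
    chains, keep, nmis = result.missing_chains.shape
    flat = result.missing_chains.reshape(chains * keep, nmis)
    picks = np.linspace(0, chains * keep - 1, m).round().astype(int)
    pids = np.unique(cohort[id_col].to_numpy())
    for t in picks:
        df = carried.copy()
        for (covariate, ppos), value in zip(result.missing_index, flat[t]):
            pid = pids[ppos]
            rows = df[id_col] == pid
            if covariate == "education":
                df.loc[rows & df["education"].isna(), "education"] = _EDU_LEVELS[int(value)]
            else:
                df.loc[rows & df[covariate].isna(), covariate] = value
        datasets.append(df)
    return datasets


def pool_fits(results: list[PosteriorSummary]) -> PosteriorSummary:
    """Pool repeated fits by mixing their chains with equal weight.

    Exact for posterior summaries of an equal-weight mixture; all fits must
    share the same coefficient structure.
    """
    names = results[0].coef_names
    for r in results[1:]:
        if r.coef_names != names or r.family != results[0].family:
            raise ValueError("cannot pool fits with different model structure")
    coef = np.concatenate([r.coef_chains for r in results], axis=0)
    tau = (
        np.concatenate([r.tau_chains for r in results], axis=0)
        if results[0].tau_chains is not None
        else None
    )
    sigma = (
        np.concatenate([r.sigma_chains for r in results], axis=0)
        if results[0].sigma_chains is not None
        else None
    )
    table, converged = _summarize(coef, names, results[0].family, tau, sigma)
    return PosteriorSummary(
        table=table,
        coef_chains=coef,
        coef_names=list(names),
        tau_chains=tau,
        missing_chains=None,
        missing_index=[],
        family=results[0].family,
        converged=converged,
        spec=results[0].spec,
        sigma_chains=sigma,
    )


def screen_interactions(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    imputation: ImputationSpec | None = None,
    m: int = 10,
) -> tuple[pd.DataFrame, PosteriorSummary]:
    """Fit with interaction terms, judge their relevance, refit without them.

    An interaction is "relevant" when its 95% credible interval excludes 0
    and its tail probability is < 0.05. The refit reuses the imputed values
    of the original model: ``m`` completed datasets are extracted, the
    reduced model is fitted on each, and the fits are pooled.
    """
    if not spec.interactions:
        raise ValueError("spec has no interaction terms to screen")
    full = fit_logistic_mixed(cohort, spec, imputation) if spec.family == "logistic" else BayesMixedModel(cohort, spec, imputation).fit()
    rows = []
    for name in full.coef_names:
        if "_x_" not in name:
            continue
        t = full.table.loc[name]
        relevant = bool(t["ci_2.5%"] > 0 or t["ci_97.5%"] < 0) and t["tail_prob"] < 0.05
        rows.append({"interaction": name, "ci_2.5%": t["ci_2.5%"], "ci_97.5%": t["ci_97.5%"],
                     "tail_prob": t["tail_prob"], "relevant": relevant})
    decision = pd.DataFrame(rows).set_index("interaction")

    reduced_spec = copy.deepcopy(spec)
    reduced_spec.interactions = ()
    if full.missing_chains is not None and len(full.missing_index):
        completed = extract_imputations(full, cohort, m=m)
        fits = [BayesMixedModel(d, reduced_spec, imputation).fit() for d in completed]
        refit = pool_fits(fits)
    else:
        refit = BayesMixedModel(cohort, reduced_spec, imputation).fit()
    return decision, refit


def fit_bmi_lmm(
    cohort: pd.DataFrame,
    exposures: tuple[str, ...],
    imputation: ImputationSpec | None = None,
    **mcmc_kw,
) -> PosteriorSummary:
    """BMI-as-outcome Bayesian linear mixed model.

    Confounders of the extensive covariate set, a diet x follow-up-time
    interaction, and a participant random intercept; incomplete covariates
    imputed simultaneously. BMI itself is dropped from the covariate side.
    """
    spec = ModelSpec(
        outcome="bmi",
        exposures=tuple(exposures),
        covariate_set="model2",
        interactions=("diet_x_time",),
        family="gaussian",
        **mcmc_kw,
    )
    model = BayesMixedModel(cohort, spec, imputation)
    # bmi cannot be both outcome and covariate
    if "bmi" in model.columns:
        j = model.columns.index("bmi")
        model.columns.pop(j)
        model.X = np.delete(model.X, j, axis=1)
        model._parts.pop("bmi", None)
    return model.fit()


def univariable_foodgroup_screen(
    baseline: pd.DataFrame,
    outcome: str = "steatosis",
) -> pd.DataFrame:
    """Cross-sectional univariable screen of energy-adjusted food groups.

    Each of the 28 food groups is energy-adjusted by the residual method,
    standardized to unit SD, and entered alone in a logistic regression of
    baseline steatosis. Returns OR per SD with a 95% confidence interval;
    degenerate (constant) groups are flagged and skipped.
    """
    import statsmodels.api as sm

    from .foodgroups import FOOD_GROUPS
    from .profiles import energy_residual

    y = baseline[outcome].to_numpy(float)
    energy = baseline["energy_kcal"].to_numpy(float)
    rows = []
    for g in FOOD_GROUPS:
        x = baseline[g].to_numpy(float)
        if np.nanstd(x) == 0:
            rows.append({"food_group": g, "or_per_sd": np.nan, "ci_2.5%": np.nan,
                         "ci_97.5%": np.nan, "degenerate": True})
            continue
        adj = energy_residual(x, energy)
        z = (adj - np.nanmean(adj)) / np.nanstd(adj)
        mask = ~np.isnan(z)
        X = sm.add_constant(z[mask])
        fit = sm.Logit(y[mask], X).fit(disp=0)
        beta = fit.params[1]
        lo, hi = fit.conf_int()[1]
        rows.append({"food_group": g, "or_per_sd": float(np.exp(beta)),
                     "ci_2.5%": float(np.exp(lo)), "ci_97.5%": float(np.exp(hi)),
                     "degenerate": False})
    return pd.DataFrame(rows).set_index("food_group")
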