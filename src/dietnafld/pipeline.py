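"""End-to-end pipeline: simulate/load -> filter -> score -> patterns -> profile -> model -> report.

Every stage writes its tabular outputs as CSV (figures always have a CSV
twin) and the run ends with a machine-readable manifest (config hash, seed,
package versions) that makes the run reproducible from config + seed alone.
Filters log record counts in and out, mirroring a study flowchart.
"""
from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import ModelSpec, fit_logistic_mixed
from .eligibility import Phenotype, apply_exclusions, classify_liver
from .factors import DietaryPatternFA, adherence_scores, name_patterns, retain_k
from .foodgroups import FOOD_GROUPS
from .profiles import spearman_profile
from .scores import score_cohort
from .simulate import SimConfig, generate_cohort

log = logging.getLogger("dietnafld")

ALL_STAGES = ("simulate", "filter", "score", "patterns", "profile", "model", "report")


@dataclass
class PipelineConfig:
    """One input source (synthetic config or cohort CSV), stage toggles, output dir."""

    sim: SimConfig | None = None
    cohort_csv: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    outdir: str = "dietnafld_output"
    seed: int = 0
    strict: bool = False
    n_factors: int = 5
    mcmc_iterations: int = 1500
    mcmc_burn_in: int = 600
    mcmc_chains: int = 2

    def __post_init__(self):
        if (self.sim is None) == (self.cohort_csv is None):
            raise ValueError("exactly one input source required: sim config or cohort CSV")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def baseline_characteristics(baseline: pd.DataFrame) -> pd.DataFrame:
    """Median [P25, P75] / percentage summary of the baseline visit."""
    rows = []

    def med(col, label):
        if col in baseline.columns:
            v = pd.to_numeric(baseline[col], errors="coerce")
            rows.append({"characteristic": label,
                         "value": f"{v.median():.2f} [{v.quantile(.25):.2f}, {v.quantile(.75):.2f}]"})

    def pct(mask, label):
        rows.append({"characteristic": label, "value": f"{100 * np.nanmean(mask):.1f}%"})

    rows.append({"characteristic": "n", "value": str(len(baseline))})
    med("age", "Age (years)")
    if "sex" in baseline.columns:
        pct((baseline["sex"] == "female").to_numpy(float), "Female (%)")
    med("bmi", "BMI (kg/m2)")
    med("energy_kcal", "Energy intake (kcal/day)")
    med("alcohol_units", "Alcohol (units/day)")
    med("physical_activity", "Physical activity (metEq h/wk)")
    if "diabetes" in baseline.columns:
        pct(pd.to_numeric(baseline["diabetes"], errors="coerce").to_numpy(float), "Diabetes mellitus (%)")
    if "hypertension" in baseline.columns:
        pct(pd.to_numeric(baseline["hypertension"], errors="coerce").to_numpy(float), "Hypertension (%)")
    if "steatosis" in baseline.columns:
        pct(baseline["steatosis"].to_numpy(float), "NAFLD (%)")
    med("lsm_kpa", "Liver stiffness (kPa)")
    return pd.DataFrame(rows)


def severity_plot(
    scores: pd.DataFrame,
    phenotypes: pd.Series,
    outdir: Path | None = None,
    filename: str = "severity",
):
    """Adherence-score distributions across no-steatosis / NAFLD / NASF groups.

    Returns the summary table (always); writes figure + CSV twin when
    ``outdir`` is given. Empty phenotype groups are omitted with a warning.
    """
    groups = [Phenotype.NO_NAFLD.value, Phenotype.NAFLD.value, Phenotype.NASF.value]
    present = []
    for g in groups:
        if (phenotypes == g).sum() == 0:
            log.warning("severity plot: phenotype group %r is empty and was omitted", g)
        else:
            present.append(g)
    rows = []
    for pat in scores.columns:
        for g in present:
            v = scores.loc[(phenotypes == g).to_numpy(bool), pat]
            rows.append({
                "pattern": pat, "group": g, "n": int(len(v)),
                "median": float(v.median()), "p25": float(v.quantile(.25)),
                "p75": float(v.quantile(.75)),
            })
    summary = pd.DataFrame(rows)
    if outdir is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(scores.columns), figsize=(3 * len(scores.columns), 3.2), sharey=True)
        axes = np.atleast_1d(axes)
        for ax, pat in zip(axes, scores.columns):
            data = [scores.loc[(phenotypes == g).to_numpy(bool), pat].dropna() for g in present]
            ax.boxplot(data, tick_labels=[g.replace("_", "\n") for g in present])
            ax.set_title(pat, fontsize=8)
        fig.tight_layout()
        fig.savefig(Path(outdir) / f"{filename}.png", dpi=120)
        plt.close(fig)
        summary.to_csv(Path(outdir) / f"{filename}.csv", index=False)
    return summary


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Deterministic given the seed. A stage failure raises with the stage
    named; outputs of completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    artifacts: dict[str, str] = {}

    def stage(name):
        def deco(fn):
            if name in stages:
                log.info("stage %s: starting", name)
                try:
                    fn()
                except Exception as exc:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return fn
        return deco

    ctx: dict = {}

    @stage("simulate")
    def _simulate():
        if config.sim is not None:
            sim = config.sim
            cohort, truth = generate_cohort(sim)
            cohort.to_csv(outdir / "cohort.csv", index=False)
            truth.to_json(outdir / "sim_truth.json")
            artifacts["cohort"] = "cohort.csv"
            ctx["cohort"] = cohort
        else:
            ctx["cohort"] = pd.read_csv(config.cohort_csv)
        log.info("cohort: %d rows", len(ctx["cohort"]))

    if "simulate" not in stages:
        if config.cohort_csv is None:
            raise ValueError("pipeline without a simulate stage needs a cohort CSV input")
        ctx["cohort"] = pd.read_csv(config.cohort_csv)

    @stage("filter")
    def _filter():
        cohort = ctx["cohort"]
        baseline = cohort[cohort["visit"] == cohort["visit"].min()]
        eligible_base, tally = apply_exclusions(baseline)
        keep = set(eligible_base["participant_id"])
        filtered = cohort[cohort["participant_id"].isin(keep)].copy()
        filtered["phenotype"] = [
            classify_liver(bool(s), l).phenotype.value
            for s, l in zip(filtered["steatosis"], filtered["lsm_kpa"])
        ]
        log.info("filter: %d -> %d baseline participants", len(baseline), len(eligible_base))
        _write_json(outdir / "exclusion_tally.json", tally.as_dict())
        artifacts["exclusion_tally"] = "exclusion_tally.json"
        ctx["cohort"] = filtered

    @stage("score")
    def _score():
        cohort = ctx["cohort"]
        scored = score_cohort(cohort)
        scored.to_csv(outdir / "apriori_scores.csv", index=False)
        artifacts["apriori_scores"] = "apriori_scores.csv"
        ctx["apriori"] = scored
        base = cohort[cohort["visit"] == cohort["visit"].min()]
        baseline_characteristics(base).to_csv(outdir / "baseline_characteristics.csv", index=False)
        artifacts["baseline_characteristics"] = "baseline_characteristics.csv"

    @stage("patterns")
    def _patterns():
        cohort = ctx["cohort"]
        base = cohort[cohort["visit"] == cohort["visit"].min()]
        fa = DietaryPatternFA(n_factors=config.n_factors).fit(base[list(FOOD_GROUPS)])
        fa = name_patterns(fa)
        fa.loadings.to_csv(outdir / "loadings.csv")
        _, scree, _ = retain_k(fa.eigenvalues)
        scree.to_csv(outdir / "scree.csv", index=False)
        scores_b, scaling = adherence_scores(fa.loadings, base[list(FOOD_GROUPS)])
        with open(outdir / "adherence_scaling.json", "w") as fh:
            fh.write(scaling.to_json())
        all_scores, _ = adherence_scores(fa.loadings, cohort[list(FOOD_GROUPS)], scaling=scaling)
        out = pd.concat(
            [cohort[["participant_id", "visit"]].reset_index(drop=True),
             all_scores.reset_index(drop=True)], axis=1,
        )
        out.to_csv(outdir / "adherence_scores.csv", index=False)
        artifacts.update({"loadings": "loadings.csv", "scree": "scree.csv",
                          "adherence_scores": "adherence_scores.csv",
                          "adherence_scaling": "adherence_scaling.json"})
        ctx["fa"] = fa
        ctx["adherence"] = out

    @stage("profile")
    def _profile():
        cohort = ctx["cohort"].reset_index(drop=True)
        base_mask = cohort["visit"] == cohort["visit"].min()
        adherence = ctx["adherence"].reset_index(drop=True)
        scores = adherence.loc[base_mask.to_numpy(), [c for c in adherence.columns if c not in ("participant_id", "visit")]]
        from .scores import NUTRIENT_COLUMNS

        nut_cols = [c for c in NUTRIENT_COLUMNS if c in cohort.columns]
        nutrients = cohort.loc[base_mask.to_numpy(), nut_cols]
        energy = cohort.loc[base_mask.to_numpy(), "energy_kcal"]
        profiles = []
        for adjust in ("none", "energy", "energy_plus_patterns"):
            profiles.append(spearman_profile(scores, nutrients, energy=energy, adjust=adjust).table)
        prof = pd.concat(profiles, ignore_index=True)
        prof.to_csv(outdir / "correlation_profile.csv", index=False)
        artifacts["correlation_profile"] = "correlation_profile.csv"

    @stage("model")
    def _model():
        cohort = ctx["cohort"].reset_index(drop=True)
        adherence = ctx["adherence"].reset_index(drop=True)
        pattern_cols = [c for c in adherence.columns if c not in ("participant_id", "visit")]
        merged = pd.concat([cohort, adherence[pattern_cols]], axis=1)
        for covariate_set in ("model1", "model2"):
            spec = ModelSpec(
                outcome="steatosis", exposures=tuple(pattern_cols),
                covariate_set=covariate_set,
                chains=config.mcmc_chains, iterations=config.mcmc_iterations,
                burn_in=config.mcmc_burn_in, seed=config.seed,
            )
            res = fit_logistic_mixed(merged, spec, strict=config.strict)
            res.table.to_csv(outdir / f"posteriori_{covariate_set}.csv")
            artifacts[f"posteriori_{covariate_set}"] = f"posteriori_{covariate_set}.csv"
        ctx["merged"] = merged

    @stage("report")
    def _report():
        cohort = ctx["cohort"].reset_index(drop=True)
        adherence = ctx["adherence"].reset_index(drop=True)
        base_mask = (cohort["visit"] == cohort["visit"].min()).to_numpy()
        pattern_cols = [c for c in adherence.columns if c not in ("participant_id", "visit")]
        if "phenotype" in cohort.columns:
            phen = cohort.loc[base_mask, "phenotype"]
        else:
            phen = pd.Series(
                [classify_liver(bool(s), l).phenotype.value
                 for s, l in zip(cohort.loc[base_mask, "steatosis"], cohort.loc[base_mask, "lsm_kpa"])],
                index=cohort.index[base_mask],
            )
        severity_plot(adherence.loc[base_mask, pattern_cols], phen, outdir=outdir)
        artifacts["severity"] = "severity.csv"

    manifest = {
        "package": "dietnafld",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": list(config.stages),
        "config_hash": hashlib.sha256(
            json.dumps({k: str(v) for k, v in vars(config).items()}, sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": artifacts,
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir
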