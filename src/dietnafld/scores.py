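"""A priori diet-quality scores: adapted MDS, Dutch guidelines (DDG), WHO.

Three pre-hypothesized indices computed from the 28 food groups plus a
nutrient vector:

* adapted Mediterranean Diet Score (MDS, 0-8): seven beneficial components
  (vegetables, legumes, fruit, nuts, whole grains, fish, MUFA:SFA ratio)
  scored 1 when at or above the sex-specific baseline median, and red meat
  scored 1 when strictly below its sex-specific median. The classical
  alcohol component is dropped (alcohol is a model covariate instead).
* Dutch Dietary Guidelines score (DDG, 0-14): fourteen absolute-threshold
  indicators (see ``data/score_thresholds.yaml``).
* WHO recommendation score (0-6): six indicators on vegetables+fruit,
  sugar, energy fractions from fat / saturated fat / trans fat, and salt.

Missing inputs never silently score 0: the affected component indicator is
None and the result is flagged incomplete.
"""
from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .foodgroups import FOOD_GROUPS

#: Canonical nutrient columns (units in the name; energy kcal/day).
NUTRIENT_COLUMNS: tuple[str, ...] = (
    "energy_kcal",
    "total_fat_g",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "trans_fat_g",
    "animal_protein_g",
    "vegetable_protein_g",
    "fibre_g",
    "mono_disaccharides_g",
    "added_sugar_g",
    "alcohol_g",
    "sodium_g",
    "potassium_mg",
    "haem_iron_mg",
    "vitamin_e_mg",
)

#: MDS component -> the quantity it is scored on. Food-group components map
#: to intake columns; the fat-quality component is the MUFA:SFA ratio.
MDS_BENEFICIAL: tuple[str, ...] = (
    "vegetables",
    "legumes",
    "fruit",
    "nuts",
    "whole_grains",
    "fish",
    "mufa_sfa_ratio",
)
MDS_HAZARDOUS: tuple[str, ...] = ("red_meat",)
MDS_COMPONENTS: tuple[str, ...] = MDS_BENEFICIAL + MDS_HAZARDOUS

DDG_COMPONENTS: tuple[str, ...] = (
    "vegetables",
    "fruit",
    "whole_grains",
    "legumes",
    "nuts",
    "fish",
    "dairy",
    "tea",
    "whole_grain_ratio",
    "unsaturated_fat_ratio",
    "red_processed_meat",
    "sugary_drinks",
    "alcohol",
    "salt",
)

WHO_COMPONENTS: tuple[str, ...] = (
    "veg_fruit",
    "sugar",
    "fat_energy_pct",
    "sfa_energy_pct",
    "trans_energy_pct",
    "salt",
)

KCAL_PER_G_FAT = 9.0


def default_thresholds() -> dict:
    ref = importlib.resources.files("dietnafld.data") / "score_thresholds.yaml"
    with importlib.resources.as_file(ref) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)


@dataclass
class ScoreResult:
    """Per-index component indicators and total."""

    index: str
    components: dict[str, int | None]
    total: int | None
    complete: bool

    @classmethod
    def from_components(cls, index: str, components: dict[str, int | None]) -> "ScoreResult":
        complete = all(v is not None for v in components.values())
        total = sum(components.values()) if complete else None
        return cls(index=index, components=components, total=total, complete=complete)


@dataclass
class MedianCutoffs:
    """Sex-specific baseline median cut-offs for the MDS components."""

    by_sex: dict[str, dict[str, float]] = field(default_factory=dict)

    def get(self, sex: str, component: str) -> float:
        s = _norm_sex(sex)
        if s not in self.by_sex:
            raise KeyError(f"no median cut-offs for sex {sex!r}")
        return self.by_sex[s][component]


def _norm_sex(sex: str) -> str:
    s = str(sex).lower()
    if s in ("female", "f", "woman", "w"):
        return "female"
    if s in ("male", "m", "man"):
        return "male"
    raise ValueError(f"unknown sex code: {sex!r}")


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def mufa_sfa_ratio(mufa: float, sfa: float) -> float:
    """MUFA:SFA ratio; infinite when SFA is zero with positive MUFA, zero when both are zero."""
    if _isnan(mufa) or _isnan(sfa):
        return float("nan")
    if sfa == 0:
        return math.inf if mufa > 0 else 0.0
    return mufa / sfa


def mds_quantities(row: pd.Series) -> dict[str, float]:
    """Component quantities the MDS is scored on, for one participant-visit."""
    q = {c: float(row[c]) for c in ("vegetables", "legumes", "fruit", "nuts", "whole_grains", "fish", "red_meat")}
    q["mufa_sfa_ratio"] = mufa_sfa_ratio(float(row["mufa_g"]), float(row["sfa_g"]))
    return q


def mds_medians(baseline: pd.DataFrame, sex_col: str = "sex") -> MedianCutoffs:
    """Sex-specific medians of the MDS component quantities on the baseline sample.

    Cut-offs must be derived from the baseline visit only; pass a table
    already restricted to baseline rows.
    """
    cutoffs = MedianCutoffs()
    sexes = baseline[sex_col].map(_norm_sex)
    for sex in ("female", "male"):
        stratum = baseline.loc[(sexes == sex).to_numpy()]
        if len(stratum) < 2:
            raise ValueError(f"sex stratum {sex!r} has fewer than 2 participants")
        med: dict[str, float] = {}
        for comp in MDS_COMPONENTS:
            if comp == "mufa_sfa_ratio":
                vals = [mufa_sfa_ratio(m, s) for m, s in zip(stratum["mufa_g"], stratum["sfa_g"])]
                med[comp] = float(pd.Series(vals).median())
            else:
                med[comp] = float(stratum[comp].median())
        cutoffs.by_sex[sex] = med
    return cutoffs


def score_mds(row: pd.Series, sex: str, cutoffs: MedianCutoffs) -> ScoreResult:
    """Adapted 8-component MDS for one participant-visit.

    Beneficial components score 1 at or above the sex-specific median;
    red meat scores 1 strictly below its median.
    """
    q = mds_quantities(row)
    comps: dict[str, int | None] = {}
    for comp in MDS_BENEFICIAL:
        v = q[comp]
        comps[comp] = None if _isnan(v) else int(v >= cutoffs.get(sex, comp))
    rm = q["red_meat"]
    comps["red_meat"] = None if _isnan(rm) else int(rm < cutoffs.get(sex, "red_meat"))
    return ScoreResult.from_components("MDS", comps)


def _ratio(numer: float, denom: float) -> float:
    # 0/0 adherence ratios score as 0: undefined adherence is not rewarded.
    if denom == 0:
        return 0.0
    return numer / denom


def score_ddg(row: pd.Series, thresholds: dict | None = None) -> ScoreResult:
    """Dutch Dietary Guidelines score (14 binary components)."""
    t = (thresholds or default_thresholds())["ddg"]
    salt_factor = (thresholds or default_thresholds()).get("salt_from_sodium_factor", 2.54)

    def get(col: str) -> float:
        v = float(row[col])
        return v

    comps: dict[str, int | None] = {}

    def ind(name: str, value: float, ok: bool) -> None:
        comps[name] = None if _isnan(value) else int(ok)

    veg = get("vegetables")
    ind("vegetables", veg, veg >= t["vegetables_min_g_day"])
    fruit = get("fruit")
    ind("fruit", fruit, fruit >= t["fruit_min_g_day"])
    wg = get("whole_grains")
    ind("whole_grains", wg, wg >= t["whole_grains_min_g_day"])
    leg = get("legumes")
    ind("legumes", leg, leg * 7 >= t["legumes_min_g_week"])
    nuts = get("nuts")
    ind("nuts", nuts, nuts >= t["nuts_min_g_day"])
    fish = get("fish")
    ind("fish", fish, fish * 7 >= t["fish_min_g_week"])
    dairy = get("low_fat_dairy") + get("high_fat_dairy")
    ind("dairy", dairy, dairy >= t["dairy_min_g_day"])
    tea = get("tea")
    ind("tea", tea, tea >= t["tea_min_ml_day"])
    rg = get("refined_grains")
    wg_ratio = float("nan") if (_isnan(wg) or _isnan(rg)) else _ratio(wg, wg + rg)
    ind("whole_grain_ratio", wg_ratio, wg_ratio >= t["whole_grain_ratio_min"])
    mufa, pufa, fat = get("mufa_g"), get("pufa_g"), get("total_fat_g")
    fat_ratio = float("nan") if any(map(_isnan, (mufa, pufa, fat))) else _ratio(mufa + pufa, fat)
    ind("unsaturated_fat_ratio", fat_ratio, fat_ratio >= t["unsaturated_fat_ratio_min"])
    meat = get("red_meat") + get("refined_or_organ_meat")
    ind("red_processed_meat", meat, meat * 7 < t["red_processed_meat_max_g_week"])
    ssb = get("sugary_drinks")
    ind("sugary_drinks", ssb, ssb <= t["sugary_drinks_max_ml_day"])
    alc = get("alcohol_g")
    ind("alcohol", alc, alc <= t["alcohol_max_g_day"])
    salt = get("sodium_g") * salt_factor
    ind("salt", salt, salt <= t["salt_max_g_day"])
    return ScoreResult.from_components("DDG", comps)


def score_who(row: pd.Series, thresholds: dict | None = None) -> ScoreResult:
    """WHO recommendation score (6 binary components).

    Energy fractions are grams x 9 kcal/g / total kcal x 100; requires
    positive energy intake.
    """
    t = (thresholds or default_thresholds())["who"]
    salt_factor = (thresholds or default_thresholds()).get("salt_from_sodium_factor", 2.54)
    energy = float(row["energy_kcal"])
    if _isnan(energy):
        raise ValueError("energy intake is missing; WHO energy-percentage components undefined")
    if energy <= 0:
        raise ValueError(f"energy intake must be positive for WHO scoring, got {energy}")

    comps: dict[str, int | None] = {}

    def ind(name: str, value: float, ok: bool) -> None:
        comps[name] = None if _isnan(value) else int(ok)

    vf = float(row["vegetables"]) + float(row["fruit"])
    ind("veg_fruit", vf, vf >= t["veg_fruit_min_g_day"])
    sugar = float(row["added_sugar_g"])
    ind("sugar", sugar, sugar < t["sugar_max_g_day"])
    for name, col, cap in (
        ("fat_energy_pct", "total_fat_g", t["fat_energy_pct_max"]),
        ("sfa_energy_pct", "sfa_g", t["sfa_energy_pct_max"]),
        ("trans_energy_pct", "trans_fat_g", t["trans_energy_pct_max"]),
    ):
        g = float(row[col])
        pct = float("nan") if _isnan(g) else g * KCAL_PER_G_FAT / energy * 100.0
        ind(name, pct, pct < cap)
    salt = float(row["sodium_g"]) * salt_factor
    ind("salt", salt, salt < t["salt_max_g_day"])
    return ScoreResult.from_components("WHO", comps)


def score_cohort(
    cohort: pd.DataFrame,
    cutoffs: MedianCutoffs | None = None,
    thresholds: dict | None = None,
    sex_col: str = "sex",
    visit_col: str = "visit",
) -> pd.DataFrame:
    """Score every participant-visit row on all three indices.

    MDS cut-offs are computed on the baseline visit (lowest visit value)
    when not supplied, and reused for the other visits.
    """
    thresholds = thresholds or default_thresholds()
    if cutoffs is None:
        baseline = cohort.loc[cohort[visit_col] == cohort[visit_col].min()]
        cutoffs = mds_medians(baseline, sex_col=sex_col)
    records = []
    for _, row in cohort.iterrows():
        mds = score_mds(row, row[sex_col], cutoffs)
        ddg = score_ddg(row, thresholds)
        who = score_who(row, thresholds)
        rec = {
            "participant_id": row.get("participant_id"),
            visit_col: row.get(visit_col),
            "mds_total": mds.total,
            "ddg_total": ddg.total,
            "who_total": who.total,
        }
        rec.update({f"mds_{k}": v for k, v in mds.components.items()})
        rec.update({f"ddg_{k}": v for k, v in ddg.components.items()})
        rec.update({f"who_{k}": v for k, v in who.components.items()})
        records.append(rec)
    return pd.DataFrame.from_records(records)
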