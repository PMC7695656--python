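"""A priori diet-quality scorers: MDS, Dutch guidelines, WHO."""
import math

import numpy as np
import pandas as pd
import pytest

from dietnafld.foodgroups import FOOD_GROUPS
from dietnafld.scores import (
    DDG_COMPONENTS,
    MDS_COMPONENTS,
    WHO_COMPONENTS,
    MedianCutoffs,
    mds_medians,
    mufa_sfa_ratio,
    score_cohort,
    score_ddg,
    score_mds,
    score_who,
)

from ._oracles import brute_ddg, brute_mds, brute_who, random_diets


def _row(**overrides) -> pd.Series:
    base = {g: 0.0 for g in FOOD_GROUPS}
    base.update(
        energy_kcal=2000.0, total_fat_g=0.0, sfa_g=0.0, mufa_g=0.0, pufa_g=0.0,
        trans_fat_g=0.0, added_sugar_g=0.0, alcohol_g=0.0, sodium_g=0.0,
    )
    base.update(overrides)
    return pd.Series(base)


def _cutoffs(value=1.0) -> MedianCutoffs:
    med = {c: value for c in MDS_COMPONENTS}
    return MedianCutoffs(by_sex={"female": dict(med), "male": dict(med)})


class TestMDS:
    def test_component_count(self):
        assert len(MDS_COMPONENTS) == 8

    def test_maximal_and_minimal_diets(self):
        cut = _cutoffs(10.0)
        high = _row(**{c: 20.0 for c in ("vegetables", "legumes", "fruit", "nuts",
                                         "whole_grains", "fish")},
                    mufa_g=40.0, sfa_g=2.0, red_meat=1.0)
        assert score_mds(high, "female", cut).total == 8
        low = _row(red_meat=50.0, sfa_g=10.0, mufa_g=1.0)
        assert score_mds(low, "male", cut).total == 0

    def test_boundary_convention_at_exact_medians(self):
        """At the median: beneficial components score 1, red meat scores 0."""
        cut = _cutoffs(5.0)
        row = _row(**{c: 5.0 for c in ("vegetables", "legumes", "fruit", "nuts",
                                       "whole_grains", "fish", "red_meat")},
                   mufa_g=5.0, sfa_g=1.0)
        res = score_mds(row, "female", cut)
        assert res.total == 7
        assert res.components["red_meat"] == 0

    def test_missing_component_marks_total_incomplete(self):
        cut = _cutoffs(5.0)
        row = _row(mufa_g=5.0, sfa_g=1.0)
        row["fish"] = np.nan
        res = score_mds(row, "female", cut)
        assert res.components["fish"] is None
        assert res.total is None and not res.complete

    @pytest.mark.parametrize("mufa,sfa,expected", [(5.0, 0.0, math.inf), (0.0, 0.0, 0.0)])
    def test_fat_ratio_degenerate_cases(self, mufa, sfa, expected):
        assert mufa_sfa_ratio(mufa, sfa) == expected


class TestMedians:
    def test_hand_computable_fixture(self):
        rows = []
        for sex, veg in [("female", 100), ("female", 200), ("female", 300),
                         ("male", 50), ("male", 150)]:
            r = _row(vegetables=veg, mufa_g=10.0, sfa_g=5.0).to_dict()
            r["sex"] = sex
            rows.append(r)
        df = pd.DataFrame(rows)
        cut = mds_medians(df)
        assert cut.get("female", "vegetables") == 200
        assert cut.get("male", "vegetables") == 100
        assert cut.get("female", "mufa_sfa_ratio") == pytest.approx(2.0)

    def test_duplicating_every_row_leaves_medians_unchanged(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(12):
            r = _row(**{g: float(rng.uniform(0, 300)) for g in FOOD_GROUPS},
                     mufa_g=float(rng.uniform(0, 50)), sfa_g=float(rng.uniform(1, 30))).to_dict()
            r["sex"] = "female" if i % 2 else "male"
            rows.append(r)
        df = pd.DataFrame(rows)
        doubled = pd.concat([df, df], ignore_index=True)
        c1, c2 = mds_medians(df), mds_medians(doubled)
        assert c1.by_sex == c2.by_sex

    def test_empty_stratum_errors(self):
        df = pd.DataFrame([{**_row().to_dict(), "sex": "female"}] * 3)
        with pytest.raises(ValueError, match="male"):
            mds_medians(df)


class TestDDG:
    def test_component_count(self):
        assert len(DDG_COMPONENTS) == 14

    def test_all_zero_diet_scores_the_four_caps(self):
        """Zero intake meets the meat, sugary-drink, alcohol and salt caps only."""
        res = score_ddg(_row())
        assert res.total == 4
        assert {k for k, v in res.components.items() if v == 1} == {
            "red_processed_meat", "sugary_drinks", "alcohol", "salt",
        }

    @pytest.mark.parametrize(
        "overrides,component,expected",
        [
            ({"vegetables": 250.0}, "vegetables", 1),
            ({"vegetables": 199.9}, "vegetables", 0),
            ({"legumes": 9.0}, "legumes", 0),       # 63 g/week < 135
            ({"legumes": 135 / 7}, "legumes", 1),
            ({"fish": 100 / 7}, "fish", 1),
            ({"low_fat_dairy": 200.0, "high_fat_dairy": 150.0}, "dairy", 1),
            ({"whole_grains": 50.0, "refined_grains": 50.0}, "whole_grain_ratio", 1),
            ({"whole_grains": 49.0, "refined_grains": 51.0}, "whole_grain_ratio", 0),
            ({"total_fat_g": 40.0, "mufa_g": 15.0, "pufa_g": 5.0}, "unsaturated_fat_ratio", 1),
            ({"red_meat": 30.0, "refined_or_organ_meat": 15.0}, "red_processed_meat", 0),
            ({"sodium_g": 6 / 2.54}, "salt", 1),
            ({"sodium_g": 2.4}, "salt", 0),         # 6.1 g salt
        ],
    )
    def test_printed_thresholds(self, overrides, component, expected):
        assert score_ddg(_row(**overrides)).components[component] == expected


class TestWHO:
    def test_component_count(self):
        assert len(WHO_COMPONENTS) == 6

    def test_degenerate_zero_intake_diet(self):
        res = score_who(_row(energy_kcal=1.0))
        assert res.total == 5
        assert res.components["veg_fruit"] == 0

    def test_vegfruit_uses_combined_intake(self):
        res = score_who(_row(vegetables=211.0, fruit=301.0))
        assert res.components["veg_fruit"] == 1

    def test_fat_energy_percentage(self):
        # 80 g fat at 2000 kcal = 36 energy% -> fails the 30% cap
        res = score_who(_row(total_fat_g=80.0, energy_kcal=2000.0))
        assert res.components["fat_energy_pct"] == 0
        res = score_who(_row(total_fat_g=60.0, energy_kcal=2000.0))  # 27%
        assert res.components["fat_energy_pct"] == 1

    def test_nonpositive_energy_is_an_error(self):
        with pytest.raises(ValueError):
            score_who(_row(energy_kcal=0.0))


class TestOracleAgreement:
    def test_brute_force_agreement_on_random_diets(self):
        """Production scorers agree exactly with plain indicator arithmetic."""
        cut_val = 150.0
        med = {c: cut_val for c in MDS_COMPONENTS}
        med["mufa_sfa_ratio"] = 1.0
        cutoffs = MedianCutoffs(by_sex={"female": med, "male": med})
        for d in random_diets(1000, seed=7):
            row = pd.Series(d)
            assert score_mds(row, "female", cutoffs).total == brute_mds(d, med)
            assert score_ddg(row).total == brute_ddg(d)
            assert score_who(row).total == brute_who(d)


class TestMonotonicity:
    @pytest.mark.parametrize("component,column", [
        ("vegetables", "vegetables"), ("fruit", "fruit"), ("nuts", "nuts"),
    ])
    def test_increasing_beneficial_quantity_never_lowers_ddg(self, component, column):
        rng = np.random.default_rng(11)
        for _ in range(50):
            d = {g: float(rng.uniform(0, 400)) for g in FOOD_GROUPS}
            d.update(total_fat_g=50.0, mufa_g=20.0, pufa_g=5.0, sfa_g=20.0,
                     trans_fat_g=1.0, energy_kcal=2000.0, added_sugar_g=5.0,
                     alcohol_g=5.0, sodium_g=1.0)
            lo = score_ddg(pd.Series(d)).total
            d[column] += float(rng.uniform(0, 400))
            hi = score_ddg(pd.Series(d)).total
            assert hi >= lo

    def test_increasing_capped_quantity_never_raises_who(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            d = _row(**{g: float(rng.uniform(0, 300)) for g in FOOD_GROUPS},
                     energy_kcal=2000.0, total_fat_g=float(rng.uniform(0, 100)),
                     sodium_g=float(rng.uniform(0, 3))).to_dict()
            lo = score_who(pd.Series(d)).total
            d["sodium_g"] += float(rng.uniform(0, 3))
            d["total_fat_g"] += float(rng.uniform(0, 50))
            hi = score_who(pd.Series(d)).total
            assert hi <= lo

    def test_rescaling_irrelevant_component_leaves_totals_unchanged(self):
        d = _row(vegetables=250.0, coffee=400.0, energy_kcal=2000.0).to_dict()
        before = score_ddg(pd.Series(d)).total
        d["coffee"] *= 10  # coffee enters no DDG component
        assert score_ddg(pd.Series(d)).total == before


def test_batch_scoring_runs_on_synthetic_cohort(small_cohort):
    cohort, _ = small_cohort
    scored = score_cohort(cohort)
    assert len(scored) == len(cohort)
    assert scored["mds_total"].between(0, 8).all()
    assert scored["ddg_total"].between(0, 14).all()
    assert scored["who_total"].between(0, 6).all()
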