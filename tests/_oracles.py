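"""Independent brute-force oracles, written separately from the production path.

Plain indicator arithmetic straight from the guideline definitions; no reuse
of package scoring code beyond shared constants for names.
"""
from __future__ import annotations

import numpy as np


def brute_mds(q: dict, medians: dict) -> int:
    """Adapted 8-component MDS: 7 beneficial at/above median, red meat below."""
    total = 0
    for comp in ("vegetables", "legumes", "fruit", "nuts", "whole_grains", "fish", "mufa_sfa_ratio"):
        if q[comp] >= medians[comp]:
            total += 1
    if q["red_meat"] < medians["red_meat"]:
        total += 1
    return total


def brute_ddg(r: dict) -> int:
    """Dutch guideline score, 14 indicators, thresholds as published."""
    t = 0
    t += r["vegetables"] >= 200
    t += r["fruit"] >= 200
    t += r["whole_grains"] >= 90
    t += r["legumes"] * 7 >= 135
    t += r["nuts"] >= 15
    t += r["fish"] * 7 >= 100
    t += (r["low_fat_dairy"] + r["high_fat_dairy"]) >= 350
    t += r["tea"] >= 150
    grains = r["whole_grains"] + r["refined_grains"]
    t += (grains > 0) and (r["whole_grains"] / grains >= 0.5)
    fat = r["total_fat_g"]
    t += (fat > 0) and ((r["mufa_g"] + r["pufa_g"]) / fat >= 0.5)
    t += (r["red_meat"] + r["refined_or_organ_meat"]) * 7 < 300
    t += r["sugary_drinks"] <= 150
    t += r["alcohol_g"] <= 10
    t += r["sodium_g"] * 2.54 <= 6
    return int(t)


def brute_who(r: dict) -> int:
    """WHO recommendation score, 6 indicators."""
    t = 0
    t += (r["vegetables"] + r["fruit"]) >= 400
    t += r["added_sugar_g"] < 10
    e = r["energy_kcal"]
    t += r["total_fat_g"] * 9 / e * 100 < 30
    t += r["sfa_g"] * 9 / e * 100 < 10
    t += r["trans_fat_g"] * 9 / e * 100 < 1
    t += r["sodium_g"] * 2.54 < 5
    return int(t)


def random_diets(n: int, seed: int = 0):
    """Random synthetic diets spanning the thresholds of every component."""
    from dietnafld.foodgroups import FOOD_GROUPS

    rng = np.random.default_rng(seed)
    diets = []
    for _ in range(n):
        d = {g: float(rng.uniform(0, 500)) for g in FOOD_GROUPS}
        d.update(
            energy_kcal=float(rng.uniform(500, 4000)),
            total_fat_g=float(rng.uniform(0, 150)),
            sfa_g=float(rng.uniform(0, 60)),
            mufa_g=float(rng.uniform(0, 60)),
            pufa_g=float(rng.uniform(0, 40)),
            trans_fat_g=float(rng.uniform(0, 5)),
            added_sugar_g=float(rng.uniform(0, 40)),
            alcohol_g=float(rng.uniform(0, 30)),
            sodium_g=float(rng.uniform(0, 4)),
        )
        d["mufa_sfa_ratio"] = d["mufa_g"] / d["sfa_g"] if d["sfa_g"] > 0 else (
            np.inf if d["mufa_g"] > 0 else 0.0
        )
        diets.append(d)
    return diets
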