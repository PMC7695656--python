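"""Canonical food-group schema and bundled reference pattern structure.

Intakes are expressed in g/day (beverages in mL/day, treated as
numerically equivalent). The 28-group schema is the level at which
FFQ items are aggregated before any scoring or pattern derivation;
an item-to-group map can be supplied as config to aggregate real
item-level data onto this schema.
"""
from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

#: Canonical 28 food groups, in fixed order.
FOOD_GROUPS: tuple[str, ...] = (
    "fruit",
    "fruit_juice",
    "nuts",
    "vegetable_oils_and_stanols",
    "margarine_or_butter",
    "tomatoes",
    "vegetables",
    "potatoes",
    "legumes",
    "whole_grains",
    "refined_grains",
    "egg_products",
    "red_meat",
    "refined_or_organ_meat",
    "poultry",
    "fish",
    "low_fat_dairy",
    "high_fat_dairy",
    "salty_snacks",
    "sauces",
    "sweet_snacks_or_desserts",
    "sugary_drinks",
    "diet_soda_or_water",
    "tea",
    "coffee",
    "wine",
    "beer_or_spirits",
    "soy_products",
)

#: Food groups reported in mL/day rather than g/day.
BEVERAGE_GROUPS: frozenset[str] = frozenset(
    {
        "fruit_juice",
        "sugary_drinks",
        "diet_soda_or_water",
        "tea",
        "coffee",
        "wine",
        "beer_or_spirits",
    }
)

#: The five population-specific dietary patterns, in reference order.
PATTERN_NAMES: tuple[str, ...] = (
    "vegetable_and_fish",
    "red_meat_and_alcohol",
    "traditional",
    "salty_snacks_and_sauces",
    "high_fat_dairy_and_refined_grains",
)

#: Absolute loading above which a food group is considered to "define" a pattern.
DEFINING_LOADING_THRESHOLD = 0.2


def _reference_table() -> pd.DataFrame:
    ref = importlib.resources.files("dietnafld.data") / "reference_loadings.csv"
    with importlib.resources.as_file(ref) as path:
        tab = pd.read_csv(path, index_col="food_group")
    return tab


def reference_loadings() -> pd.DataFrame:
    """Bundled 28x5 reference factor-loading matrix.

    Rows are the canonical food groups, columns the five patterns.
    Entries not reported for a pattern are zero.
    """
    tab = _reference_table()
    lam = tab[list(PATTERN_NAMES)]
    assert list(lam.index) == list(FOOD_GROUPS)
    return lam.copy()


def reference_median_intakes() -> pd.DataFrame:
    """Median and interquartile range of daily intake per food group (g or mL)."""
    return _reference_table()[["median", "p25", "p75"]].copy()


def validate_foodgroup_frame(df: pd.DataFrame, where: str = "table") -> None:
    """Check that ``df`` carries exactly the canonical food-group columns."""
    missing = [g for g in FOOD_GROUPS if g not in df.columns]
    if missing:
        raise KeyError(f"{where} is missing food-group columns: {missing}")


def aggregate_items(items: pd.DataFrame, item_to_group: dict[str, str]) -> pd.DataFrame:
    """Aggregate item-level intakes (columns = FFQ items) onto the 28-group schema.

    Parameters
    ----------
    items
        One row per participant-visit, columns are item names, values g/day.
    item_to_group
        Mapping from item name to canonical food-group name.

    Returns
    -------
    DataFrame with one column per canonical food group (groups with no
    mapped item are zero-filled), same index as ``items``.
    """
    bad = sorted(set(item_to_group.values()) - set(FOOD_GROUPS))
    if bad:
        raise ValueError(f"item_to_group maps onto unknown food groups: {bad}")
    out = pd.DataFrame(0.0, index=items.index, columns=list(FOOD_GROUPS))
    for item, group in item_to_group.items():
        if item in items.columns:
            out[group] = out[group] + items[item].fillna(0.0).to_numpy(float)
    return out


def foodgroup_matrix(df: pd.DataFrame) -> np.ndarray:
    """Extract the n x 28 intake matrix in canonical column order."""
    validate_foodgroup_frame(df)
    return df[list(FOOD_GROUPS)].to_numpy(float)
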