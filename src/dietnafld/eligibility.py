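"""Cohort eligibility rules and liver-phenotype classification.

Implements the screening cascade of a population FFQ/elastography cohort:
FFQ reliability by reported energy, transient-elastography (TE) reliability,
alcohol-misuse thresholds, known steatogenic exposures, and the liver
phenotype taxonomy (no steatosis / NAFLD / NASF) with the 8 kPa liver
stiffness cut-off used as a fibrosis proxy.

Exclusion attribution is first-failing-rule in a fixed, documented order so
the tally reproduces a flowchart: each excluded participant counts exactly
once.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

# FFQ reliability bounds on reported energy intake, kcal/day (inclusive).
KCAL_MIN = 500.0
KCAL_MAX = 7500.0

# TE reliability: IQR/median > 0.30 is unreliable, but only when the median
# liver stiffness is >= 7.1 kPa; a failed exam is >= 10 attempts, no reading.
TE_IQR_RATIO_MAX = 0.30
TE_RATIO_APPLIES_FROM_KPA = 7.1
TE_FAILURE_ATTEMPTS = 10

# Alcohol misuse, units/day (1 unit = 10 g ethanol).
ALCOHOL_LIMIT_FEMALE = 2.0
ALCOHOL_LIMIT_MALE = 3.0

# Liver stiffness cut-off (kPa) proxying fibrosis.
LSM_FIBROSIS_CUTOFF = 8.0


class Phenotype(str, Enum):
    """Liver phenotype from ultrasound steatosis and liver stiffness."""

    NO_NAFLD = "no_NAFLD"
    NAFLD = "NAFLD"
    NASF = "NASF"
    EXCLUDED_HIGH_LSM = "excluded_high_LSM_without_steatosis"


@dataclass(frozen=True)
class LiverPhenotype:
    steatosis: bool
    lsm: float | None
    phenotype: Phenotype
    #: True when steatosis is present but LSM is missing, so the fibrosis
    #: proxy could not be evaluated and the participant is kept as NAFLD.
    lsm_missing_flag: bool = False


#: Exclusion rules in cascade order (first failing rule is attributed).
EXCLUSION_RULES: tuple[str, ...] = (
    "missing_ultrasound",
    "ffq_missing_or_unreliable",
    "te_unreliable",
    "te_failure",
    "viral_hepatitis",
    "alcohol_misuse",
    "steatogenic_drugs",
    "intracardiac_device",
    "high_lsm_no_steatosis",
)


@dataclass
class ExclusionTally:
    counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


def _is_absent(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def kcal_reliable(energy: float | None) -> bool:
    """FFQ is reliable iff reported energy is within [500, 7500] kcal/day.

    A missing energy value (missing FFQ) is unreliable. Negative energy is a
    validation error rather than an exclusion.
    """
    if _is_absent(energy):
        return False
    if energy < 0:
        raise ValueError(f"energy intake must be non-negative, got {energy}")
    return KCAL_MIN <= energy <= KCAL_MAX


def te_reliable(
    lsm_median: float | None,
    iqr: float | None = None,
    n_attempts: int | None = None,
) -> bool:
    """Transient-elastography reliability.

    Unreliable iff IQR/median > 0.30 in an exam whose median stiffness is
    >= 7.1 kPa. An exam with no reading after >= 10 attempts is a failure
    (also returns False); with fewer recorded attempts and no reading the
    exam is treated as not performed and reliability is not the blocker.
    """
    if _is_absent(lsm_median):
        if n_attempts is not None and n_attempts >= TE_FAILURE_ATTEMPTS:
            return False
        return True
    if lsm_median <= 0:
        raise ValueError(f"median LSM must be positive, got {lsm_median}")
    if _is_absent(iqr):
        return True
    if lsm_median >= TE_RATIO_APPLIES_FROM_KPA and iqr / lsm_median > TE_IQR_RATIO_MAX:
        return False
    return True


def alcohol_misuse(units_per_day: float, sex: str) -> bool:
    """Alcohol misuse: >= 2 units/day in women, >= 3 units/day in men."""
    if units_per_day < 0:
        raise ValueError(f"alcohol intake must be non-negative, got {units_per_day}")
    s = str(sex).lower()
    if s in ("female", "f", "woman", "w"):
        return units_per_day >= ALCOHOL_LIMIT_FEMALE
    if s in ("male", "m", "man"):
        return units_per_day >= ALCOHOL_LIMIT_MALE
    raise ValueError(f"unknown sex code: {sex!r}")


def classify_liver(steatosis: bool, lsm: float | None) -> LiverPhenotype:
    """Map (ultrasound steatosis, liver stiffness) to a liver phenotype.

    NASF = steatosis with LSM >= 8 kPa; high stiffness without steatosis is
    excluded from a NAFLD-focused analysis; steatosis with missing LSM is
    retained as NAFLD with the fibrosis proxy flagged unknown.
    """
    if _is_absent(lsm):
        if steatosis:
            return LiverPhenotype(True, None, Phenotype.NAFLD, lsm_missing_flag=True)
        return LiverPhenotype(False, None, Phenotype.NO_NAFLD)
    if steatosis:
        if lsm >= LSM_FIBROSIS_CUTOFF:
            return LiverPhenotype(True, lsm, Phenotype.NASF)
        return LiverPhenotype(True, lsm, Phenotype.NAFLD)
    if lsm >= LSM_FIBROSIS_CUTOFF:
        return LiverPhenotype(False, lsm, Phenotype.EXCLUDED_HIGH_LSM)
    return LiverPhenotype(False, lsm, Phenotype.NO_NAFLD)


_REQUIRED_COLUMNS = (
    "has_ultrasound",
    "energy_kcal",
    "lsm_kpa",
    "lsm_iqr_kpa",
    "te_attempts",
    "viral_hepatitis",
    "alcohol_units",
    "sex",
    "steatogenic_drugs",
    "intracardiac_device",
    "steatosis",
)


def _first_failing_rule(row: pd.Series) -> str | None:
    if not bool(row["has_ultrasound"]):
        return "missing_ultrasound"
    if not kcal_reliable(row["energy_kcal"]):
        return "ffq_missing_or_unreliable"
    lsm = row["lsm_kpa"]
    iqr = row["lsm_iqr_kpa"]
    attempts = row["te_attempts"]
    attempts = None if _is_absent(attempts) else int(attempts)
    if not _is_absent(lsm) and not te_reliable(lsm, iqr, attempts):
        return "te_unreliable"
    if _is_absent(lsm) and attempts is not None and attempts >= TE_FAILURE_ATTEMPTS:
        return "te_failure"
    if bool(row["viral_hepatitis"]):
        return "viral_hepatitis"
    if alcohol_misuse(float(row["alcohol_units"]), row["sex"]):
        return "alcohol_misuse"
    if bool(row["steatogenic_drugs"]):
        return "steatogenic_drugs"
    if bool(row["intracardiac_device"]):
        return "intracardiac_device"
    pheno = classify_liver(bool(row["steatosis"]), lsm)
    if pheno.phenotype is Phenotype.EXCLUDED_HIGH_LSM:
        return "high_lsm_no_steatosis"
    return None


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the eligibility cascade to a baseline cohort table.

    Each participant is attributed to the first rule that fails, in
    ``EXCLUSION_RULES`` order. Returns the eligible rows (copy, with a
    ``phenotype`` column added) and the per-rule tally.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing required columns: {missing}")
    tally = ExclusionTally()
    keep = []
    phenos = []
    for idx, row in cohort.iterrows():
        rule = _first_failing_rule(row)
        if rule is None:
            keep.append(idx)
            phenos.append(classify_liver(bool(row["steatosis"]), row["lsm_kpa"]).phenotype.value)
        else:
            tally.counts[rule] += 1
    out = cohort.loc[keep].copy()
    out["phenotype"] = phenos
    return out, tally
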