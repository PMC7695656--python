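"""Nutrient correlation profiling of dietary patterns.

Two pieces: the residual method of energy adjustment (a nutrient is
regressed on total energy intake by least squares and replaced by its
residual, re-centred at the predicted value for mean energy so the adjusted
variable keeps the original scale), and Spearman rank-correlation profiles
of pattern adherence scores against nutrients in three variants —
unadjusted, energy-adjusted, and (for the factor-analytic patterns)
energy-plus-other-patterns-adjusted.

The adjusted variants are Spearman correlations of the *residualized raw*
values; a rank-based partial-correlation alternative is available behind
the ``method="partial"`` flag. Complete-case analysis throughout; ties get
average ranks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def energy_residual(values: np.ndarray, energy: np.ndarray) -> np.ndarray:
    """Residual-method energy adjustment.

    Least-squares residuals of ``values`` on ``energy``, plus the predicted
    value at mean energy (which equals the mean of ``values``), so the
    adjusted series is on the original scale and uncorrelated with energy.
    """
    v = np.asarray(values, float)
    e = np.asarray(energy, float)
    if v.shape != e.shape:
        raise ValueError(f"values and energy have different lengths: {v.shape} vs {e.shape}")
    mask = ~(np.isnan(v) | np.isnan(e))
    if mask.sum() < 3:
        raise ValueError("need at least 3 complete pairs for energy adjustment")
    if np.var(e[mask]) == 0:
        raise ValueError("energy has zero variance; residual adjustment undefined")
    ec = e[mask] - e[mask].mean()
    beta = (ec @ (v[mask] - v[mask].mean())) / (ec @ ec)
    out = np.full_like(v, np.nan)
    out[mask] = v[mask] - beta * ec  # residual + prediction at mean energy
    return out


def _residualize_on(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of values on a covariate matrix (with intercept), re-centred."""
    v = np.asarray(values, float)
    X = np.column_stack([np.ones(len(v)), np.asarray(covariates, float)])
    mask = ~(np.isnan(v) | np.isnan(X).any(axis=1))
    beta, *_ = np.linalg.lstsq(X[mask], v[mask], rcond=None)
    out = np.full_like(v, np.nan)
    out[mask] = v[mask] - X[mask] @ beta + v[mask].mean()
    return out


@dataclass
class CorrelationProfile:
    """Long-format Spearman correlation profile."""

    table: pd.DataFrame  # columns: pattern, nutrient, adjustment, rho, p_value, n

    def pivot(self, adjustment: str) -> pd.DataFrame:
        sub = self.table[self.table["adjustment"] == adjustment]
        return sub.pivot(index="nutrient", columns="pattern", values="rho")


_ADJUSTMENTS = ("none", "energy", "energy_plus_patterns")


def spearman_profile(
    scores: pd.DataFrame,
    nutrients: pd.DataFrame,
    energy: pd.Series | None = None,
    adjust: str = "none",
    method: str = "residual",
) -> CorrelationProfile:
    """Spearman correlations of each pattern score with each nutrient.

    Parameters
    ----------
    scores
        One column per pattern adherence score, one row per participant.
    nutrients
        Nutrient columns, same index.
    energy
        Total energy intake (kcal/day); required for the adjusted variants.
    adjust
        ``"none"``, ``"energy"``, or ``"energy_plus_patterns"`` — the last
        residualizes each nutrient on energy *and*, per target pattern, on
        the other pattern scores.
    method
        ``"residual"`` (Spearman on residualized raw values, default) or
        ``"partial"`` (rank-based partial correlation).
    """
    if adjust not in _ADJUSTMENTS:
        raise ValueError(f"adjust must be one of {_ADJUSTMENTS}, got {adjust!r}")
    if method not in ("residual", "partial"):
        raise ValueError(f"method must be 'residual' or 'partial', got {method!r}")
    if adjust != "none" and energy is None:
        raise ValueError("energy series required for adjusted profiles")
    common = scores.index.intersection(nutrients.index)
    scores = scores.loc[common]
    nutrients = nutrients.loc[common]
    if energy is not None:
        energy = energy.loc[common]

    rows = []
    for pat in scores.columns:
        s = scores[pat].to_numpy(float)
        for nut in nutrients.columns:
            v = nutrients[nut].to_numpy(float)
            if adjust == "none":
                covs = None
            elif adjust == "energy":
                covs = energy.to_numpy(float)[:, None]
            else:
                others = [c for c in scores.columns if c != pat]
                covs = np.column_stack(
                    [energy.to_numpy(float)] + [scores[c].to_numpy(float) for c in others]
                )
            if covs is None:
                x, y = s, v
            elif method == "residual":
                x, y = s, _residualize_on(v, covs)
            else:  # rank-based partial correlation
                mask0 = ~(np.isnan(s) | np.isnan(v) | np.isnan(covs).any(axis=1))
                rs = stats.rankdata(s[mask0])
                rv = stats.rankdata(v[mask0])
                rc = np.column_stack([stats.rankdata(covs[mask0, j]) for j in range(covs.shape[1])])
                x = np.full_like(s, np.nan)
                y = np.full_like(v, np.nan)
                x[mask0] = rs - np.column_stack([np.ones(mask0.sum()), rc]) @ np.linalg.lstsq(
                    np.column_stack([np.ones(mask0.sum()), rc]), rs, rcond=None
                )[0] + rs.mean()
                y[mask0] = rv - np.column_stack([np.ones(mask0.sum()), rc]) @ np.linalg.lstsq(
                    np.column_stack([np.ones(mask0.sum()), rc]), rv, rcond=None
                )[0] + rv.mean()
            mask = ~(np.isnan(x) | np.isnan(y))
            n = int(mask.sum())
            if n < 3:
                rows.append(
                    {"pattern": pat, "nutrient": nut, "adjustment": adjust,
                     "rho": np.nan, "p_value": np.nan, "n": n}
                )
                continue
            if method == "partial" and covs is not None:
                rho, p = stats.pearsonr(x[mask], y[mask])
            else:
                rho, p = stats.spearmanr(x[mask], y[mask])
            rows.append(
                {"pattern": pat, "nutrient": nut, "adjustment": adjust,
                 "rho": float(rho), "p_value": float(p), "n": n}
            )
    return CorrelationProfile(table=pd.DataFrame(rows))


def profile_figure(profile: CorrelationProfile, pattern: str, ax=None):
    """Grouped bar chart of a pattern's nutrient correlations by adjustment."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = profile.table[profile.table["pattern"] == pattern]
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    adjustments = [a for a in _ADJUSTMENTS if a in set(sub["adjustment"])]
    nutrients = list(dict.fromkeys(sub["nutrient"]))
    width = 0.8 / max(len(adjustments), 1)
    xs = np.arange(len(nutrients))
    for i, adj in enumerate(adjustments):
        vals = [
            sub[(sub["adjustment"] == adj) & (sub["nutrient"] == n)]["rho"].mean()
            for n in nutrients
        ]
        ax.bar(xs + i * width, vals, width=width, label=adj)
    ax.set_xticks(xs + width * (len(adjustments) - 1) / 2)
    ax.set_xticklabels(nutrients, rotation=90, fontsize=7)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("Spearman rho")
    ax.set_title(pattern)
    ax.legend(fontsize=7)
    return ax
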