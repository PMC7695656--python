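"""A posteriori dietary patterns: minres factor analysis with varimax rotation.

The population-specific patterns are derived by exploratory factor analysis
of the correlation matrix of the 28 food-group intakes at baseline:

* minimum-residual (minres / unweighted least squares) extraction — the
  loading matrix ``L`` minimizes the sum of squared *off-diagonal* residuals
  of ``R - L L'``;
* orthogonal varimax rotation, with columns re-sorted by explained variance
  and per-column sign fixed so the largest-magnitude loading is positive;
* the number of factors is chosen from the bend in the scree plot (a
  maximum-curvature heuristic is provided); the replication configuration
  fixes k = 5;
* per-participant adherence scores are the loadings applied to the observed
  (raw) food-group intakes, standardized against the *baseline* mean/SD,
  and follow-up scores reuse the baseline scaling parameters so baseline
  and follow-up adherence are comparable.

Factor analysis runs on the correlation matrix rather than the covariance
matrix because intakes are on wildly different scales (coffee in hundreds
of mL/day, sauces in single grams).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .foodgroups import FOOD_GROUPS, PATTERN_NAMES

__all__ = [
    "FactorSolution",
    "AdherenceScaling",
    "DietaryPatternFA",
    "fit_minres",
    "varimax",
    "retain_k",
    "adherence_scores",
    "tucker_congruence",
    "match_factors",
    "minres_objective",
]


def minres_objective(R: np.ndarray, L: np.ndarray) -> float:
    """Sum of squared off-diagonal residuals of ``R - L L'``."""
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return float(np.sum(resid**2))


@dataclass
class FactorSolution:
    """Result of a factor extraction (optionally rotated)."""

    loadings: pd.DataFrame            # p x k
    uniquenesses: pd.Series           # length p, 1 - communality
    explained_variance_share: pd.Series   # % of total variance per factor
    eigenvalues: np.ndarray           # of the input correlation matrix
    rotation: str                     # "none" or "varimax"
    objective: float                  # minres objective at the solution
    n_obs: int | None = None

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def defining_groups(self, threshold: float = 0.2) -> dict[str, list[str]]:
        """Food groups with |loading| above ``threshold``, per pattern."""
        out = {}
        for col in self.loadings.columns:
            mask = self.loadings[col].abs() > threshold
            out[col] = list(self.loadings.index[mask])
        return out


def _validate_corr(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, float)
    p = R.shape[0]
    if R.shape != (p, p):
        raise ValueError(f"correlation matrix must be square, got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.min(linalg.eigvalsh(R)) < -1e-6:
        raise ValueError("correlation matrix is not positive semidefinite within tolerance")
    return R


def _loadings_given_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenstructure of the reduced correlation matrix R - diag(psi)."""
    Rstar = R - np.diag(psi)
    vals, vecs = linalg.eigh(Rstar)
    order = np.argsort(vals)[::-1][:k]
    lam = np.sqrt(np.clip(vals[order], 0.0, None))
    return vecs[:, order] * lam


def fit_minres(
    R: np.ndarray | pd.DataFrame,
    k: int,
    names: list[str] | None = None,
    max_iter: int = 2000,
) -> FactorSolution:
    """Minimum-residual factor extraction (unrotated).

    The uniquenesses are optimized by L-BFGS-B starting from 1 minus the
    squared multiple correlation of each variable, which makes the solution
    deterministic; given the uniquenesses the loadings are the top-k
    eigenstructure of the reduced correlation matrix.
    """
    if isinstance(R, pd.DataFrame):
        names = list(R.index)
        R = R.to_numpy(float)
    R = _validate_corr(R)
    p = R.shape[0]
    if not (1 <= k < p):
        raise ValueError(f"number of factors must satisfy 1 <= k < {p}, got {k} (over-factored)")
    if names is None:
        names = [f"var{i+1}" for i in range(p)]

    # start: psi = 1 - SMC (squared multiple correlation), the classical rule
    try:
        Rinv = linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
    except linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.005, 1.0)

    def obj(psi: np.ndarray) -> float:
        return minres_objective(R, _loadings_given_psi(R, psi, k))

    res = optimize.minimize(
        obj,
        psi0,
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.fun > obj(psi0):
        raise RuntimeError(
            f"minres did not converge within {max_iter} iterations; residual norm {res.fun:.3e}"
        )
    L = _loadings_given_psi(R, res.x, k)
    eigenvalues = np.sort(linalg.eigvalsh(R))[::-1]
    communality = (L**2).sum(axis=1)
    share = (L**2).sum(axis=0) / p * 100.0
    cols = [f"factor{i+1}" for i in range(k)]
    return FactorSolution(
        loadings=pd.DataFrame(L, index=names, columns=cols),
        uniquenesses=pd.Series(np.clip(1.0 - communality, 0.0, 1.0), index=names),
        explained_variance_share=pd.Series(share, index=cols),
        eigenvalues=eigenvalues,
        rotation="none",
        objective=float(res.fun),
        n_obs=None,
    )


def _varimax_rotation(L: np.ndarray, normalize: bool = True, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal rotation matrix maximizing the varimax criterion (Kaiser-normalized)."""
    p, k = L.shape
    if k < 2:
        return np.eye(k)
    X = L.copy()
    if normalize:
        h = np.sqrt((X**2).sum(axis=1))
        h[h == 0] = 1.0
        X = X / h[:, None]
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Z = X @ T
        B = X.T @ (Z**3 - Z @ np.diag((Z**2).sum(axis=0)) / p)
        U, s, Vt = linalg.svd(B)
        T = U @ Vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return T


def varimax_criterion(L: np.ndarray) -> float:
    """The varimax objective: sum over factors of the variance of squared loadings."""
    Z2 = np.asarray(L) ** 2
    return float(np.sum(Z2.var(axis=0)))


def varimax(solution: FactorSolution) -> FactorSolution:
    """Varimax-rotate a factor solution.

    Columns are re-sorted by explained variance and each column's sign is
    fixed so its largest-magnitude loading is positive. Communalities (and
    hence ``L L'``) are preserved exactly by the orthogonal rotation.
    """
    L = solution.loadings.to_numpy(float)
    p, k = L.shape
    T = _varimax_rotation(L)
    Lr = L @ T
    ss = (Lr**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    Lr = Lr[:, order]
    for j in range(k):
        i = np.argmax(np.abs(Lr[:, j]))
        if Lr[i, j] < 0:
            Lr[:, j] = -Lr[:, j]
    share = (Lr**2).sum(axis=0) / p * 100.0
    cols = [f"factor{i+1}" for i in range(k)]
    names = list(solution.loadings.index)
    R_obj = solution.objective  # orthogonal rotation leaves L L' unchanged
    return FactorSolution(
        loadings=pd.DataFrame(Lr, index=names, columns=cols),
        uniquenesses=solution.uniquenesses.copy(),
        explained_variance_share=pd.Series(share, index=cols),
        eigenvalues=solution.eigenvalues,
        rotation="varimax",
        objective=R_obj,
        n_obs=solution.n_obs,
    )


def retain_k(eigenvalues: np.ndarray, override: int | None = None) -> tuple[int, pd.DataFrame, bool]:
    """Scree-based factor retention.

    Returns ``(suggested_k, scree_table, clear_elbow)``. The heuristic takes
    the eigenvalue index of maximum curvature (second difference) and retains
    the factors before the bend; an elbow is "clear" when the maximum
    curvature is at least twice the runner-up. ``override`` (e.g. 5 for the
    replication configuration) wins when given, but the scree table is
    always returned.
    """
    e = np.asarray(eigenvalues, float)
    if np.any(np.diff(e) > 1e-10):
        raise ValueError("eigenvalues must be sorted in descending order")
    scree = pd.DataFrame(
        {
            "component": np.arange(1, len(e) + 1),
            "eigenvalue": e,
            "cumulative_share_pct": np.cumsum(e) / e.sum() * 100.0,
        }
    )
    if len(e) < 3:
        k = 1
        clear = False
    else:
        d2 = e[:-2] - 2 * e[1:-1] + e[2:]  # curvature at positions 2..p-1
        j = int(np.argmax(d2))
        k = j + 1  # factors before the bend
        rest = np.delete(d2, j)
        clear = bool(len(rest) == 0 or d2[j] >= 2 * np.max(rest))
    if override is not None:
        return int(override), scree, clear
    return k, scree, clear


@dataclass
class AdherenceScaling:
    """Baseline mean/SD used to standardize adherence scores."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self):
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"adherence scaling SD must be positive; offending patterns: {bad}")

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.to_dict(), "sd": self.sd.to_dict()})

    @classmethod
    def from_json(cls, s: str) -> "AdherenceScaling":
        d = json.loads(s)
        return cls(mean=pd.Series(d["mean"]), sd=pd.Series(d["sd"]))


def adherence_scores(
    loadings: pd.DataFrame,
    foodgroups: pd.DataFrame,
    scaling: AdherenceScaling | None = None,
    standardize_inputs: bool = False,
) -> tuple[pd.DataFrame, AdherenceScaling]:
    """Per-participant pattern adherence: loadings applied to observed intakes.

    ``raw_score = x' L`` per participant. When ``scaling`` is absent (the
    baseline path) the scores are standardized to mean 0 / SD 1 and the
    scaling parameters returned; when present (the follow-up path) it is
    applied unchanged. ``standardize_inputs`` z-scores the food groups
    before multiplication (alternative reading of the procedure; off by
    default).
    """
    missing = [g for g in loadings.index if g not in foodgroups.columns]
    if missing:
        raise KeyError(f"food-group table is missing pattern groups: {missing}")
    X = foodgroups[list(loadings.index)].to_numpy(float)
    if standardize_inputs:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    raw = X @ loadings.to_numpy(float)
    raw = pd.DataFrame(raw, index=foodgroups.index, columns=list(loadings.columns))
    if scaling is None:
        mean = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=0)
        scaling = AdherenceScaling(mean=mean, sd=sd)
    scores = (raw - scaling.mean) / scaling.sd
    return scores, scaling


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine similarity of loading vectors)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 0.0
    return float(x @ y / denom)


def match_factors(
    estimated: pd.DataFrame, reference: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimally match estimated factors to reference factors.

    Hungarian assignment on absolute Tucker congruence, then sign
    alignment. Returns ``(permutation, signs, congruences)`` such that
    ``estimated.iloc[:, permutation] * signs`` is aligned column-wise to
    ``reference`` and ``congruences[j]`` is the (signed, post-alignment)
    congruence of reference column j.
    """
    from scipy.optimize import linear_sum_assignment

    A = estimated.loc[reference.index].to_numpy(float)
    B = reference.to_numpy(float)
    k = B.shape[1]
    C = np.zeros((k, A.shape[1]))
    for j in range(k):
        for m in range(A.shape[1]):
            C[j, m] = tucker_congruence(B[:, j], A[:, m])
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(k, int)
    signs = np.empty(k)
    cong = np.empty(k)
    for r, c in zip(rows, cols):
        perm[r] = c
        signs[r] = 1.0 if C[r, c] >= 0 else -1.0
        cong[r] = abs(C[r, c])
    return perm, signs, cong


class DietaryPatternFA:
    """Factor-analytic dietary-pattern model (statsmodels-style).

    Parameters
    ----------
    n_factors
        Number of patterns to retain; ``None`` uses the scree heuristic.
    rotation
        ``"varimax"`` (default) or ``"none"``.

    ``fit`` accepts a food-group intake table (one row per participant at
    baseline) and returns a :class:`FactorSolution`.
    """

    def __init__(self, n_factors: int | None = 5, rotation: str = "varimax"):
        if rotation not in ("varimax", "none"):
            raise ValueError(f"unknown rotation {rotation!r}")
        self.n_factors = n_factors
        self.rotation = rotation

    def fit(self, foodgroups: pd.DataFrame) -> FactorSolution:
        cols = [g for g in FOOD_GROUPS if g in foodgroups.columns]
        if len(cols) != len(FOOD_GROUPS):
            cols = list(foodgroups.columns)
        X = foodgroups[cols].to_numpy(float)
        R = np.corrcoef(X, rowvar=False)
        eigenvalues = np.sort(linalg.eigvalsh(R))[::-1]
        k = self.n_factors
        if k is None:
            k, _, _ = retain_k(eigenvalues)
        sol = fit_minres(pd.DataFrame(R, index=cols, columns=cols), k)
        if self.rotation == "varimax":
            sol = varimax(sol)
        sol.n_obs = len(foodgroups)
        return sol


def name_patterns(solution: FactorSolution, reference: pd.DataFrame | None = None) -> FactorSolution:
    """Rename factor columns by best congruence match to the reference patterns."""
    from . import foodgroups as fg

    if reference is None:
        reference = fg.reference_loadings()
    perm, signs, _ = match_factors(solution.loadings, reference)
    L = solution.loadings.to_numpy(float)[:, perm] * signs
    cols = list(PATTERN_NAMES)
    out = FactorSolution(
        loadings=pd.DataFrame(L, index=solution.loadings.index, columns=cols),
        uniquenesses=solution.uniquenesses.copy(),
        explained_variance_share=pd.Series(
            (L**2).sum(axis=0) / L.shape[0] * 100.0, index=cols
        ),
        eigenvalues=solution.eigenvalues,
        rotation=solution.rotation,
        objective=solution.objective,
        n_obs=solution.n_obs,
    )
    return out
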