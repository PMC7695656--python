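"""Minres factor extraction, varimax rotation, scree retention, adherence scores."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from dietnafld.factors import (
    AdherenceScaling,
    DietaryPatternFA,
    adherence_scores,
    fit_minres,
    match_factors,
    minres_objective,
    retain_k,
    tucker_congruence,
    varimax,
    varimax_criterion,
)
from dietnafld.foodgroups import reference_loadings
from dietnafld.simulate import generate_foodgroups


def _corr_from_loadings(L):
    R = L @ L.T
    np.fill_diagonal(R, 1.0)
    return R


class TestMinres:
    def test_exact_one_factor_structure_is_recovered(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])[:, None]
        sol = fit_minres(_corr_from_loadings(lam), 1)
        got = sol.loadings.to_numpy().ravel()
        sign = np.sign(got[np.argmax(np.abs(got))] * lam[np.argmax(np.abs(lam)), 0])
        assert np.abs(sign * got - lam.ravel()).max() < 1e-6
        assert sol.objective < 1e-12

    def test_identity_matrix_gives_null_loadings(self):
        sol = fit_minres(np.eye(6), 1)
        assert np.abs(sol.loadings.to_numpy()).max() < 1e-3

    def test_objective_matches_independent_minimizer(self):
        """Minres objective equals a general-purpose free-parameter optimum."""
        rng = np.random.default_rng(42)
        for _ in range(3):
            Lt = rng.uniform(-0.6, 0.6, (6, 2))
            psi = np.clip(1 - (Lt**2).sum(1), 0.4, None)
            R = Lt @ Lt.T + np.diag(psi)
            E = rng.normal(0, 0.03, (6, 6))
            E = (E + E.T) / 2
            np.fill_diagonal(E, 0)
            R = R + E
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            sol = fit_minres(R, 2)
            # the check compares like with like only for interior solutions
            assert sol.communalities.max() < 0.9
            best = np.inf
            for _ in range(8):
                x0 = rng.standard_normal(12) * 0.4
                r = optimize.minimize(
                    lambda x: minres_objective(R, x.reshape(6, 2)), x0,
                    method="BFGS", options={"gtol": 1e-14, "maxiter": 10000},
                )
                best = min(best, r.fun)
            assert abs(sol.objective - best) < 1e-8

    def test_overfactored_request_errors(self):
        with pytest.raises(ValueError, match="over-factored"):
            fit_minres(np.eye(6), 6)

    def test_nonsymmetric_input_rejected(self):
        R = np.eye(4)
        R[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            fit_minres(R, 1)

    def test_uniqueness_plus_communality_is_one(self):
        fg = generate_foodgroups(2000, mode="linear", seed=9)
        sol = DietaryPatternFA(n_factors=5, rotation="none").fit(fg)
        total = sol.communalities + sol.uniquenesses
        assert np.allclose(total, 1.0, atol=0.02)


class TestVarimax:
    def test_single_factor_is_fixed_point_up_to_sign(self):
        lam = np.array([0.8, -0.7, 0.6])[:, None]
        sol = fit_minres(_corr_from_loadings(np.abs(lam)), 1)
        rotated = varimax(sol)
        assert np.allclose(np.abs(rotated.loadings), np.abs(sol.loadings), atol=1e-10)

    def test_rotation_preserves_communalities_and_improves_criterion(self):
        rng = np.random.default_rng(5)
        L = rng.uniform(-0.6, 0.6, (10, 3))
        sol = fit_minres(_corr_from_loadings(L) + np.eye(10) * 1e-9, 3)
        rotated = varimax(sol)
        L0 = sol.loadings.to_numpy()
        L1 = rotated.loadings.to_numpy()
        assert np.abs(L1 @ L1.T - L0 @ L0.T).max() < 1e-10
        assert varimax_criterion(L1) >= varimax_criterion(L0) - 1e-12

    def test_columns_sorted_and_sign_fixed(self):
        fg = generate_foodgroups(3000, mode="linear", seed=2)
        sol = varimax(DietaryPatternFA(n_factors=5, rotation="none").fit(fg))
        shares = sol.explained_variance_share.to_numpy()
        assert np.all(np.diff(shares) <= 1e-12)
        for col in sol.loadings.columns:
            v = sol.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestScree:
    def test_single_dominant_eigenvalue_suggests_one_factor(self):
        e = np.array([10.0] + [1.0] * 9)
        k, scree, clear = retain_k(e)
        assert k == 1 and clear
        assert len(scree) == 10

    def test_monotone_geometric_decay_flags_no_clear_elbow(self):
        e = 10 * 0.8 ** np.arange(12)
        k, _, clear = retain_k(e)
        assert k == 1  # curvature of a geometric sequence peaks at the start
        assert not clear

    def test_replication_override_wins(self):
        e = np.array([10.0] + [1.0] * 27)
        k, scree, _ = retain_k(e, override=5)
        assert k == 5
        assert scree["eigenvalue"].iloc[0] == 10.0

    def test_unsorted_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            retain_k(np.array([1.0, 2.0, 0.5]))


class TestAdherence:
    def test_zero_intake_maps_to_minus_mean_over_sd(self):
        L = reference_loadings()
        fg = generate_foodgroups(200, mode="positive", seed=1)
        _, scaling = adherence_scores(L, fg)
        zero = fg.iloc[:1].copy() * 0.0
        scores, _ = adherence_scores(L, zero, scaling=scaling)
        expected = (-scaling.mean / scaling.sd).to_numpy()
        assert np.allclose(scores.iloc[0].to_numpy(), expected)

    def test_baseline_scores_standardized_exactly(self):
        L = reference_loadings()
        fg = generate_foodgroups(500, mode="positive", seed=4)
        scores, _ = adherence_scores(L, fg)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(scores.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_followup_reuses_baseline_scaling_hand_computed(self):
        L = pd.DataFrame({"p1": [0.5, 0.5]}, index=["fruit", "fish"])
        base = pd.DataFrame({"fruit": [100.0, 200.0, 300.0], "fish": [10.0, 20.0, 30.0]})
        _, scaling = adherence_scores(L, base)
        fu = pd.DataFrame({"fruit": [150.0, 250.0, 50.0], "fish": [15.0, 25.0, 5.0]})
        scores, _ = adherence_scores(L, fu, scaling=scaling)
        raw = fu.to_numpy() @ L.to_numpy()
        expected = (raw.ravel() - scaling.mean["p1"]) / scaling.sd["p1"]
        assert np.allclose(scores["p1"].to_numpy(), expected)
        assert abs(scores["p1"].mean()) > 1e-9  # follow-up mean is generally nonzero

    def test_name_mismatch_lists_offending_groups(self):
        L = pd.DataFrame({"p1": [0.5]}, index=["dragonfruit"])
        fg = pd.DataFrame({"fruit": [1.0]})
        with pytest.raises(KeyError, match="dragonfruit"):
            adherence_scores(L, fg)

    def test_scaling_roundtrips_through_json(self):
        s = AdherenceScaling(mean=pd.Series({"a": 1.0}), sd=pd.Series({"a": 2.0}))
        s2 = AdherenceScaling.from_json(s.to_json())
        assert s2.mean["a"] == 1.0 and s2.sd["a"] == 2.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            AdherenceScaling(mean=pd.Series({"a": 0.0}), sd=pd.Series({"a": 0.0}))


class TestCongruence:
    def test_congruence_of_identical_and_opposite_vectors(self):
        v = np.array([0.5, -0.2, 0.7])
        assert tucker_congruence(v, v) == pytest.approx(1.0)
        assert tucker_congruence(v, -v) == pytest.approx(-1.0)

    def test_matching_recovers_a_known_permutation_with_signs(self):
        rng = np.random.default_rng(8)
        ref = pd.DataFrame(rng.uniform(-0.6, 0.6, (12, 3)), columns=list("abc"))
        perm_true = [2, 0, 1]
        signs_true = np.array([1.0, -1.0, 1.0])
        est = ref.to_numpy()[:, perm_true] * signs_true
        est = pd.DataFrame(est + rng.normal(0, 0.01, est.shape), index=ref.index)
        perm, signs, cong = match_factors(est, ref)
        aligned = est.to_numpy()[:, perm] * signs
        for j in range(3):
            assert tucker_congruence(aligned[:, j], ref.to_numpy()[:, j]) > 0.99
        assert np.all(cong > 0.99)
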