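"""Watson loss, analytic gradients and the projected-gradient optimizer."""

import numpy as np
import pytest

from daa.datamodel import MultiViewData, ViewKey
from daa.model import (
    EPS_Q,
    FitConfig,
    WatsonProblem,
    _total_loss,
    _update_C,
    _update_S_view,
    fit_daa,
    fit_with_restarts,
    gradients,
    reconstruct,
    watson_loss,
)

from conftest import make_instance, random_simplex


def naive_watson_loss(X, X_hat):
    total = 0.0
    for n in range(X.shape[1]):
        x, xh = X[:, n], X_hat[:, n]
        total -= (x @ xh) ** 2 / (xh @ xh + EPS_Q)
    return total


class TestReconstruct:
    def test_selection_case(self):
        rng = np.random.default_rng(0)
        Xf = rng.standard_normal((3, 6))
        Xf /= np.linalg.norm(Xf, axis=0)
        C = np.zeros((6, 2))
        C[1, 0] = 1.0  # archetype 0 = sample 1
        C[4, 1] = 1.0
        S = np.zeros((2, 6))
        S[0, :3] = 1.0
        S[1, 3:] = 1.0
        X_hat = reconstruct(Xf, C, S)
        for n in range(3):
            np.testing.assert_allclose(X_hat[:, n], Xf[:, 1])
        for n in range(3, 6):
            np.testing.assert_allclose(X_hat[:, n], Xf[:, 4])

    def test_single_archetype_columns_identical(self):
        data, C, S = make_instance(1, K=1)
        k = data.keys[0]
        X_hat = reconstruct(data.x_tilde_flipped[k], C, S)
        np.testing.assert_allclose(X_hat, X_hat[:, :1] @ np.ones((1, 12)))

    @pytest.mark.parametrize("seed", [2, 3])
    def test_columns_are_convex_combinations(self, seed):
        data, C, S = make_instance(seed, N=15, K=3)
        k = data.keys[0]
        Xf = data.x_tilde_flipped[k]
        X_hat = reconstruct(Xf, C, S)
        A = Xf @ C
        for n in range(15):  # per-column oracle
            np.testing.assert_allclose(X_hat[:, n], A @ S[:, n], atol=1e-14)
        assert np.all(np.linalg.norm(X_hat, axis=0) <= 1 + 1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            reconstruct(np.ones((3, 5)), np.ones((4, 2)), np.ones((2, 5)))


class TestWatsonLoss:
    def _unit(self, seed, D=3, N=8):
        X = np.random.default_rng(seed).standard_normal((D, N))
        return X / np.linalg.norm(X, axis=0)

    def test_perfect_reconstruction(self):
        X = self._unit(0)
        assert watson_loss(X, X) == pytest.approx(-8, rel=1e-9)

    def test_polarity_invariance(self):
        X = self._unit(1)
        assert watson_loss(X, -X) == pytest.approx(-8, rel=1e-9)

    def test_orthogonal_reconstruction(self):
        X = np.array([[1.0, 1.0], [0.0, 0.0]]) / 1.0
        X_hat = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert watson_loss(X, X_hat) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((3, 10))
        X_hat = rng.standard_normal((3, 10))
        assert watson_loss(X, X_hat) == pytest.approx(
            naive_watson_loss(X, X_hat), rel=1e-12)


class TestGradients:
    @pytest.mark.parametrize("seed", range(20))
    def test_finite_difference_oracle(self, seed):
        """Analytic gradients of the minimized loss match central finite
        differences on random instances (mandatory sign/orientation check)."""
        data, C, S = make_instance(seed, D=3, N=12, K=2)
        k = data.keys[0]
        X, Xf = data.views[k], data.x_tilde_flipped[k]
        gC, gS = gradients(X, Xf, C, S)
        h = 1e-6

        def loss(C_, S_):
            return watson_loss(X, Xf @ C_ @ S_)

        fdC = np.zeros_like(C)
        for i in range(C.shape[0]):
            for j in range(C.shape[1]):
                dp, dm = C.copy(), C.copy()
                dp[i, j] += h
                dm[i, j] -= h
                fdC[i, j] = (loss(dp, S) - loss(dm, S)) / (2 * h)
        fdS = np.zeros_like(S)
        for i in range(S.shape[0]):
            for j in range(S.shape[1]):
                dp, dm = S.copy(), S.copy()
                dp[i, j] += h
                dm[i, j] -= h
                fdS[i, j] = (loss(C, dp) - loss(C, dm)) / (2 * h)
        assert np.abs(gC - fdC).max() < 1e-5
        assert np.abs(gS - fdS).max() < 1e-5

    def test_homogeneity_in_data_scale(self):
        """The loss is quadratic in X, so X -> cX scales both gradients
        by c^2."""
        data, C, S = make_instance(5)
        k = data.keys[0]
        X, Xf = data.views[k], data.x_tilde_flipped[k]
        gC1, gS1 = gradients(X, Xf, C, S)
        c = 3.7
        gC2, gS2 = gradients(c * X, Xf, C, S)
        np.testing.assert_allclose(gC2, c**2 * gC1, rtol=1e-9)
        np.testing.assert_allclose(gS2, c**2 * gS1, rtol=1e-9)

    def test_exact_match_is_simplex_stationary(self):
        """When a mixing column exactly reproduces a sample's direction,
        its loss term sits at the per-sample maximum kappa_n and no
        feasible simplex direction improves it."""
        rng = np.random.default_rng(9)
        Xf = rng.standard_normal((3, 4))
        Xf /= np.linalg.norm(Xf, axis=0)
        C = np.eye(4)[:, :2]  # archetypes = samples 0 and 1
        S = np.zeros((2, 4))
        S[0, 0] = 1.0  # sample 0 reconstructed exactly by archetype 0
        S[:, 1:] = 0.5
        kappa = np.array([2.0, 1.0, 1.0, 1.0])
        X = Xf * np.sqrt(kappa)
        z = X[:, 0] @ (Xf @ C @ S)[:, 0]
        q = np.sum((Xf @ C @ S)[:, 0] ** 2)
        assert z**2 / q == pytest.approx(kappa[0], rel=1e-9)
        _, gS = gradients(X, Xf, C, S)
        # feasible directions at the vertex e_0: d = e_k - e_0
        for k in range(1, 2):
            directional = gS[k, 0] - gS[0, 0]
            assert directional >= -1e-9


class TestUpdates:
    def test_zero_gradient_keeps_C_and_grows_step(self, monkeypatch):
        data, C, S = make_instance(11, N=10, K=2)
        problem = WatsonProblem(data)
        monkeypatch.setattr(problem, "grad_C",
                            lambda C_, S_: np.zeros_like(C_))
        cache = problem.make_cache(C)
        loss = _total_loss(problem, [S], cache)
        cfg = FitConfig(n_archetypes=2)
        C2, mu2, loss2, _ = _update_C(problem, C, [S], 1.0, loss, cache, cfg)
        np.testing.assert_array_equal(C2, C)
        assert mu2 == pytest.approx(1.1)
        assert loss2 == loss

    def test_accepted_C_step_strictly_lowers_loss(self):
        data, C, S = make_instance(12, N=20, K=3)
        problem = WatsonProblem(data)
        cache = problem.make_cache(C)
        loss = _total_loss(problem, [S], cache)
        cfg = FitConfig(n_archetypes=3)
        C2, mu2, loss2, _ = _update_C(problem, C, [S], 1.0, loss, cache, cfg)
        if not np.array_equal(C2, C):
            assert loss2 < loss
        # simplex preserved
        np.testing.assert_allclose(C2.sum(axis=0), 1.0, atol=1e-8)
        assert np.all(C2 >= 0)

    def test_S_sweep_never_increases_per_sample_terms(self):
        data, C, S = make_instance(13, N=25, K=3)
        problem = WatsonProblem(data)
        cache = problem.make_cache(C)
        before = problem.loss_terms(0, S, cache)
        S2, mu2, after = _update_S_view(problem, 0, S, np.ones(25), cache)
        assert np.all(after <= before + 1e-15)
        np.testing.assert_allclose(S2.sum(axis=0), 1.0, atol=1e-8)
        assert np.all(S2 >= 0)

    def test_one_hot_on_matching_archetype_is_fixed_point(self):
        """A sample lying exactly on archetype k keeps its one-hot column
        through an S sweep (no feasible improvement exists)."""
        rng = np.random.default_rng(14)
        Xf = rng.standard_normal((3, 5))
        Xf /= np.linalg.norm(Xf, axis=0)
        data = MultiViewData.from_raw({ViewKey("m", "s"): Xf})
        k = data.keys[0]
        Xf_p = data.x_tilde_flipped[k]
        C = np.zeros((5, 2))
        C[0, 0] = 1.0
        C[3, 1] = 1.0
        S = random_simplex(rng, (2, 5))
        S[:, 0] = [1.0, 0.0]  # sample 0 = archetype 0 exactly
        problem = WatsonProblem(data)
        cache = problem.make_cache(C)
        S2, _, _ = _update_S_view(problem, 0, S, np.ones(5), cache)
        np.testing.assert_allclose(S2[:, 0], [1.0, 0.0], atol=1e-12)


class TestFit:
    def test_monotone_trace_and_simplex_conservation(self, octant_noisy):
        data, _ = octant_noisy
        cfg = FitConfig(n_archetypes=3, max_iter=50, seed=0)
        model = fit_daa(data, cfg)
        assert np.all(np.diff(model.loss_trace) <= 1e-12)
        np.testing.assert_allclose(model.C.sum(axis=0), 1.0, atol=1e-8)
        assert np.all(model.C >= 0)
        for S in model.S.values():
            np.testing.assert_allclose(S.sum(axis=0), 1.0, atol=1e-8)
            assert np.all(S >= 0)

    def test_k_exceeding_n_rejected(self, octant_small):
        data, _ = octant_small
        cfg = FitConfig(n_archetypes=301)
        with pytest.raises(ValueError, match="exceeds"):
            fit_daa(data, cfg)

    def test_single_archetype_matches_grid_oracle(self):
        """K = 1 reduces to the best single Watson direction; a coarse grid
        search over S^2 gives an independent estimate of that optimum."""
        from daa.synthetic import SyntheticSpec, simulate

        spec = SyntheticSpec(family="octant", n_samples=40, noise_sd=0.0, seed=5)
        X, _ = simulate(spec)
        data = MultiViewData.from_raw({ViewKey("m", "s"): X})
        cfg = FitConfig(n_archetypes=1, n_restarts=5, n_outer=1,
                        max_iter=2000, rel_tol=1e-10, seed=0)
        best, _ = fit_with_restarts(data, cfg)
        k = data.keys[0]
        Xs = data.views[k]
        # grid over the sphere (polar parametrization)
        best_grid = 0.0
        for theta in np.linspace(0, np.pi, 120):
            for phi in np.linspace(0, 2 * np.pi, 240, endpoint=False):
                mu = np.array([np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi), np.cos(theta)])
                val = -np.sum((mu @ Xs) ** 2)
                best_grid = min(best_grid, val)
        assert best.loss == pytest.approx(best_grid, rel=2e-2)
        # and never better than the unconstrained optimum (the dominant
        # eigenvalue of X X^T, which the grid approximates from above)
        top = np.linalg.eigvalsh(Xs @ Xs.T)[-1]
        assert best.loss >= -top - 1e-9

    def test_identical_views_get_identical_mixing(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((3, 40))
        raw = {ViewKey("a", "s"): X, ViewKey("b", "s"): X.copy()}
        data = MultiViewData.from_raw(raw)
        cfg = FitConfig(n_archetypes=2, max_iter=100, seed=1)
        model = fit_daa(data, cfg)
        Sa, Sb = model.S[ViewKey("a", "s")], model.S[ViewKey("b", "s")]
        np.testing.assert_allclose(Sa, Sb, atol=1e-12)

    def test_polarity_invariance_of_fitted_loss(self):
        """Randomly negating data columns leaves the fitted loss unchanged
        to machine precision."""
        rng = np.random.default_rng(16)
        X = rng.standard_normal((3, 60))
        signs = rng.choice([-1.0, 1.0], size=60)
        cfg = FitConfig(n_archetypes=3, max_iter=150, seed=2)
        m1 = fit_daa(MultiViewData.from_raw({ViewKey("m", "s"): X}), cfg)
        m2 = fit_daa(MultiViewData.from_raw({ViewKey("m", "s"): X * signs}), cfg)
        assert abs(m1.loss - m2.loss) < 1e-9


class TestRestarts:
    def test_single_restart_equals_one_fit(self, octant_small):
        data, _ = octant_small
        cfg = FitConfig(n_archetypes=2, n_restarts=1, n_outer=1,
                        max_iter=60, seed=3)
        best, outer = fit_with_restarts(data, cfg)
        assert len(outer) == 1
        # reproduce the spawned stream by hand
        rng = np.random.default_rng(
            np.random.SeedSequence(3).spawn(1)[0].spawn(1)[0])
        direct = fit_daa(data, cfg, rng=rng)
        assert best.loss == pytest.approx(direct.loss, abs=0)

    def test_more_restarts_never_worse(self, octant_small):
        data, _ = octant_small
        losses = {}
        for r in (2, 8):
            cfg = FitConfig(n_archetypes=3, n_restarts=r, n_outer=1,
                            max_iter=60, seed=4)
            best, _ = fit_with_restarts(data, cfg)
            losses[r] = best.loss
        assert losses[8] <= losses[2]

    def test_outer_models_are_consistent_on_easy_data(self, octant_small):
        from daa.evaluation import consistency_protocol

        data, _ = octant_small
        cfg = FitConfig(n_archetypes=3, n_restarts=5, n_outer=3,
                        max_iter=200, seed=5)
        _, outer = fit_with_restarts(data, cfg)
        report = consistency_protocol(outer)
        assert report["mean_nmi"] > 0.9


class TestSharingModes:
    def _multicondition_data(self, seed=17, N=30):
        rng = np.random.default_rng(seed)
        raw = {}
        for b in ("s1", "s2"):
            for c in ("c1", "c2"):
                raw[ViewKey("eeg", b, c)] = rng.standard_normal((3, N))
        return MultiViewData.from_raw(raw)

    def test_concat_conditions_stacks_generator(self):
        data = self._multicondition_data()
        cfg = FitConfig(n_archetypes=2, n_restarts=1, n_outer=1, max_iter=30,
                        seed=0, sharing_mode="concat_conditions")
        best, _ = fit_with_restarts(data, cfg)
        assert best.C.shape == (60, 2)  # 2 conditions x 30 samples
        assert set(best.S) == {ViewKey("eeg", "s1"), ViewKey("eeg", "s2")}
        assert best.condition_slices["c1"] == slice(0, 30)
        assert best.condition_slices["c2"] == slice(30, 60)

    def test_no_correspondence_gives_per_view_generators(self):
        data = self._multicondition_data()
        cfg = FitConfig(n_archetypes=2, n_restarts=1, n_outer=1, max_iter=30,
                        seed=0, sharing_mode="no_correspondence")
        best, _ = fit_with_restarts(data, cfg)
        assert isinstance(best.C, dict)
        assert set(best.C) == set(data.views)

    def test_flexibility_ordering_of_losses(self):
        """The fully independent model is at least as good as the shared-C
        model, which is at least as good as the condition-concatenated
        model (nested constraint sets, up to restart noise)."""
        data = self._multicondition_data(N=40)
        losses = {}
        for mode in ("concat_conditions", "per_condition_S", "no_correspondence"):
            cfg = FitConfig(n_archetypes=2, n_restarts=4, n_outer=1,
                            max_iter=200, seed=1, sharing_mode=mode)
            best, _ = fit_with_restarts(data, cfg)
            losses[mode] = best.loss
        assert losses["no_correspondence"] <= losses["per_condition_S"] + 1e-6
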