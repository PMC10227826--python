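"""Unit and property tests for the NVSA/BSD optimizer building blocks."""

import itertools

import numpy as np
import pytest

from nvsa.optimizers import (ObjectiveSpec, OptimizerConfig, Population,
                             SearchSpace, VibrationParams, activation_matrix,
                             bernstein_rho, boundary_control, greedy_selection,
                             initialize_population, optimize, permutation_pair,
                             search_scale_bsd, search_scale_nvsa,
                             trial_vectors_bsd, trial_vectors_nvsa,
                             update_best, vibration_rho)


# ---------------------------------------------------------------------------
# search space and initialisation
# ---------------------------------------------------------------------------

class TestSearchSpace:
    def test_validation(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([0.0, np.inf]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            SearchSpace(np.array([1.0]), np.array([0.0]))

    def test_initialize_within_bounds(self, rng):
        space = SearchSpace.cube(0.0, 1.0, 3)
        P = initialize_population(space, 5, rng)
        assert P.shape == (5, 3)
        assert np.all(P >= 0.0) and np.all(P <= 1.0)

    def test_initialize_degenerate_interval(self, rng):
        space = SearchSpace(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        P = initialize_population(space, 4, rng)
        assert np.all(P == 2.0)

    def test_initialize_seed_determinism(self):
        space = SearchSpace.cube(-5.0, 5.0, 4)
        P1 = initialize_population(space, 6, np.random.default_rng(7))
        P2 = initialize_population(space, 6, np.random.default_rng(7))
        np.testing.assert_array_equal(P1, P2)


class TestUpdateBest:
    def _pop(self, fit, best=np.inf):
        fit = np.asarray(fit, dtype=float)
        P = np.arange(fit.size * 2, dtype=float).reshape(fit.size, 2)
        return Population(P=P, fitP=fit, best_sol=best, best_PV=P[0].copy())

    def test_argmin(self):
        pop = update_best(self._pop([3.0, 1.0, 2.0]))
        assert pop.best_sol == 1.0
        np.testing.assert_array_equal(pop.best_PV, pop.P[1])

    def test_tie_breaks_to_lowest_index(self):
        pop = update_best(self._pop([1.0, 1.0, 5.0]))
        np.testing.assert_array_equal(pop.best_PV, pop.P[0])

    def test_best_is_monotone(self):
        pop = self._pop([0.7, 0.9], best=0.5)
        stored = pop.best_PV.copy()
        update_best(pop)
        assert pop.best_sol == 0.5
        np.testing.assert_array_equal(pop.best_PV, stored)

    def test_empty_population_errors(self):
        pop = Population(P=np.empty((0, 2)), fitP=np.empty(0),
                         best_sol=np.inf, best_PV=np.empty(2))
        with pytest.raises(ValueError):
            update_best(pop)


# ---------------------------------------------------------------------------
# crossover-ratio generators
# ---------------------------------------------------------------------------

class TestRho:
    @pytest.mark.parametrize("k,beta,expected", [
        (1, 0.0, 1.0),       # (1-b)^2 at the endpoint
        (2, 0.5, 0.5),       # 2 b (1-b)
        (3, 0.5, 0.25),      # b^2
    ])
    def test_bernstein_cases(self, stub_rng_factory, k, beta, expected):
        assert bernstein_rho(stub_rng_factory(k, beta)) == pytest.approx(
            expected, abs=1e-15)

    def test_bernstein_range(self, rng):
        draws = np.array([bernstein_rho(rng) for _ in range(2000)])
        assert np.all((draws >= 0.0) & (draws <= 1.0))

    def test_vibration_clips_negative_dip(self, stub_rng_factory):
        # k4 == k5 makes the vibration term H = e^(1/Pv) dominate:
        # rho_raw = e^(1/1000) - e^(1/4) = -0.28302... -> clipped to 0
        stub = stub_rng_factory(np.array([0.0, 0.5, 0.0, 0.3, 0.3]))
        assert vibration_rho(VibrationParams(), stub) == 0.0

    def test_vibration_pinned_value(self, stub_rng_factory):
        # k1=0.5, Pv=4 (k2=0.5), G=1000 (k3=0), k4=1, k5=0:
        # rho = e^(1/1000) + 0.5 - e^(1/1004)
        stub = stub_rng_factory(np.array([0.5, 0.5, 0.0, 1.0, 0.0]))
        expected = np.exp(1e-3) + 0.5 - np.exp(1.0 / 1004.0)
        got = vibration_rho(VibrationParams(), stub)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.5000039888, abs=1e-9)

    def test_vibration_always_in_unit_interval(self, rng):
        vp = VibrationParams()
        draws = np.array([vibration_rho(vp, rng) for _ in range(100_000)])
        assert np.all((draws >= 0.0) & (draws <= 1.0))

    def test_vibration_mean_band(self, rng):
        # Monte-Carlo band frozen from the formula itself (analytic mean of
        # the 2 k1 (1-k1) hump is 1/3; the vibration dip pulls it slightly
        # below after clipping).
        vp = VibrationParams()
        draws = np.fromiter((vibration_rho(vp, rng) for _ in range(200_000)),
                            dtype=float)
        assert 0.25 <= draws.mean() <= 0.45

    def test_vibration_param_validation(self):
        with pytest.raises(ValueError):
            VibrationParams(a=0.0)
        with pytest.raises(ValueError):
            VibrationParams(c=6.0, d=5.0)


class TestActivationMatrix:
    @pytest.mark.parametrize("rho,expected_ones", [
        (1.0, 6),   # full activation
        (0.5, 3),   # ceil(0.5 * 6)
        (0.0, 1),   # minimum-activation floor
    ])
    def test_row_counts(self, rng, rho, expected_ones):
        M = activation_matrix(4, 6, lambda g: rho, rng)
        assert M.shape == (4, 6)
        assert set(np.unique(M)) <= {0.0, 1.0}
        np.testing.assert_array_equal(M.sum(axis=1), expected_ones)

    def test_columns_are_random(self, rng):
        cols = np.zeros(8)
        for _ in range(200):
            cols += activation_matrix(1, 8, lambda g: 0.25, rng)[0]
        assert np.all(cols > 0)  # every column activated at least once


class TestSearchScale:
    def test_bsd_row_broadcast_branch(self, stub_rng_factory, rng):
        eta = rng.random(5)
        lam = rng.standard_normal(5)
        stub = stub_rng_factory(0.1, 0.9, eta, lam)  # u < v
        F = search_scale_bsd(4, 5, stub)
        assert np.all(F >= 0.0)
        for i in range(1, 4):
            np.testing.assert_array_equal(F[i], F[0])
        np.testing.assert_allclose(F[0], eta ** 3 * np.abs(lam ** 3))

    def test_bsd_column_broadcast_branch(self, stub_rng_factory, rng):
        lam = rng.standard_normal(4)
        stub = stub_rng_factory(0.9, 0.1, lam)  # u >= v
        F = search_scale_bsd(4, 5, stub)
        for j in range(1, 5):
            np.testing.assert_array_equal(F[:, j], F[:, 0])
        np.testing.assert_allclose(F[:, 0], lam ** 3)

    def test_nvsa_uniform_branch(self, stub_rng_factory, rng):
        eta = rng.random((6, 3))
        stub = stub_rng_factory(0.2, 0.5, eta)  # u^3 = 0.008 < v
        F = search_scale_nvsa(6, 3, stub)
        assert np.all((F >= 0.0) & (F <= 1.0))
        np.testing.assert_allclose(F, eta ** 3)

    def test_nvsa_normal_branch_moments(self):
        rng = np.random.default_rng(3)
        # force the normal branch by redrawing until u^3 >= v
        while True:
            state = rng.bit_generator.state
            u, v = rng.random(), rng.random()
            if u ** 3 >= v:
                rng.bit_generator.state = state
                break
        F = search_scale_nvsa(400, 250, rng)
        n = F.size
        assert abs(F.mean()) < 3.0 / np.sqrt(n)
        assert abs(F.std() - 1.0) < 0.02

    def test_nvsa_entries_independent_across_rows(self, stub_rng_factory, rng):
        # unlike the BSD broadcast, rows differ
        eta = rng.random((5, 4))
        F = search_scale_nvsa(5, 4, stub_rng_factory(0.1, 0.9, eta))
        assert not np.allclose(F[0], F[1])


class TestPermutationPair:
    def test_elementwise_constraints(self, rng):
        idx = np.arange(4)
        for _ in range(2000):
            L1, L2 = permutation_pair(4, rng)
            assert not np.any(L1 == idx)
            assert not np.any(L1 == L2)
            assert sorted(L1) == list(range(4))
            assert sorted(L2) == list(range(4))

    def test_membership_in_brute_force_valid_set(self, rng):
        # enumerate every valid (L1, L2) pair for N=5 and check returned
        # pairs against that set
        idx = np.arange(5)
        valid = set()
        for L1 in itertools.permutations(range(5)):
            if any(L1[i] == i for i in range(5)):
                continue
            for L2 in itertools.permutations(range(5)):
                if any(L1[i] == L2[i] for i in range(5)):
                    continue
                valid.add((L1, tuple(L2)))
        assert valid
        for _ in range(500):
            L1, L2 = permutation_pair(5, rng)
            assert (tuple(L1), tuple(L2)) in valid

    def test_small_population_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_pair(3, rng)


# ---------------------------------------------------------------------------
# trial vectors
# ---------------------------------------------------------------------------

def _random_state(rng, N=6, D=4):
    P = rng.uniform(-3, 3, (N, D))
    M = (rng.random((N, D)) < 0.5).astype(float)
    M[:, 0] = 1.0  # keep at least one active dim per row
    F = rng.standard_normal((N, D))
    best = rng.uniform(-3, 3, D)
    L1, L2 = permutation_pair(N, rng)
    return P, M, F, best, L1, L2


class TestTrialVectors:
    def test_bsd_matches_scalar_oracle(self, rng, stub_rng_factory):
        N, D = 6, 4
        P, M, F, best, L1, L2 = _random_state(rng, N, D)
        W = rng.random((N, D))
        wstar = rng.random(N)
        T = trial_vectors_bsd(P, M, F, best, L1, L2,
                              stub_rng_factory(W, wstar))
        # independent scalar loop-nest implementation of the same recipe
        expected = np.empty((N, D))
        for i in range(N):
            w3 = wstar[i] ** 3
            for j in range(D):
                e = W[i, j] * P[L1[i], j] + (1 - W[i, j]) * P[L2[i], j]
                expected[i, j] = P[i, j] + M[i, j] * F[i, j] * (
                    w3 * e + (1 - w3) * best[j] - P[i, j])
        np.testing.assert_allclose(T, expected, atol=1e-12)

    def test_nvsa_matches_scalar_oracle(self, rng, stub_rng_factory):
        N, D = 6, 4
        P, M, F, best, L1, L2 = _random_state(rng, N, D)
        s = rng.standard_normal((N, D))
        w1, w2, w3 = (rng.random((N, D)) for _ in range(3))
        T = trial_vectors_nvsa(P, M, F, best, L1, L2,
                               stub_rng_factory(s, w1, w2, w3))
        expected = np.empty((N, D))
        for i in range(N):
            for j in range(D):
                donor = (F[i, j] * (s[i, j] * w1[i, j] * P[L1[i], j]
                                    + w2[i, j] * P[L2[i], j])
                         + w3[i, j] * best[j])
                expected[i, j] = P[i, j] + M[i, j] * (donor - P[i, j])
        np.testing.assert_allclose(T, expected, atol=1e-12)

    def test_nvsa_scalar_hand_value(self, stub_rng_factory):
        # D=1, N=4, every draw pinned to printed constants
        P = np.array([[2.0], [-1.0], [0.5], [3.0]])
        M = np.ones((4, 1))
        F = np.full((4, 1), 2.0)
        best = np.array([1.0])
        L1 = np.array([1, 2, 3, 0])
        L2 = np.array([2, 3, 0, 1])
        s = np.full((4, 1), 0.5)
        w1 = np.full((4, 1), 0.4)
        w2 = np.full((4, 1), 0.3)
        w3 = np.full((4, 1), 0.2)
        T = trial_vectors_nvsa(P, M, F, best, L1, L2,
                               stub_rng_factory(s, w1, w2, w3))
        # row 0 by hand: 2*(0.5*0.4*(-1) + 0.3*0.5) + 0.2*1 = 0.1
        assert T[0, 0] == pytest.approx(0.1, abs=1e-12)

    def test_inactive_mask_preserves_parent(self, rng):
        P, _, F, best, L1, L2 = _random_state(rng)
        M = np.zeros_like(P)
        np.testing.assert_array_equal(
            trial_vectors_bsd(P, M, F, best, L1, L2, rng), P)
        np.testing.assert_array_equal(
            trial_vectors_nvsa(P, M, F, best, L1, L2, rng), P)

    def test_bsd_endpoints(self, rng, stub_rng_factory):
        P, _, _, best, L1, L2 = _random_state(rng)
        M = np.ones_like(P)
        F = np.ones_like(P)
        W = rng.random(P.shape)
        # w* = 1 -> T = E
        T = trial_vectors_bsd(P, M, F, best, L1, L2,
                              stub_rng_factory(W, np.ones(P.shape[0])))
        np.testing.assert_allclose(T, W * P[L1] + (1 - W) * P[L2], atol=1e-12)
        # w* = 0 -> every row = best
        T = trial_vectors_bsd(P, M, F, best, L1, L2,
                              stub_rng_factory(W, np.zeros(P.shape[0])))
        np.testing.assert_allclose(T, np.tile(best, (P.shape[0], 1)),
                                   atol=1e-12)

    def test_nvsa_forced_best_endpoint(self, rng, stub_rng_factory):
        P, _, _, best, L1, L2 = _random_state(rng)
        ones = np.ones_like(P)
        T = trial_vectors_nvsa(P, ones, ones, best, L1, L2,
                               stub_rng_factory(np.zeros_like(P),
                                                np.full_like(P, 0.7),
                                                np.zeros_like(P),
                                                np.ones_like(P)))
        np.testing.assert_allclose(T, np.tile(best, (P.shape[0], 1)),
                                   atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        P, M, F, best, L1, L2 = _random_state(rng)
        with pytest.raises(ValueError):
            trial_vectors_nvsa(P, M[:, :2], F, best, L1, L2, rng)
        with pytest.raises(ValueError):
            trial_vectors_bsd(P, M, F, best[:-1], L1, L2, rng)


class TestBoundaryAndSelection:
    def test_boundary_repairs_into_bounds(self, rng):
        space = SearchSpace.cube(-1.0, 1.0, 3)
        T = rng.uniform(-5, 5, (10, 3))
        out = boundary_control(T, space, rng)
        assert np.all(out >= -1.0) and np.all(out <= 1.0)
        inside = (T >= -1.0) & (T <= 1.0)
        np.testing.assert_array_equal(out[inside], T[inside])

    def test_boundary_identity_on_feasible(self, rng):
        space = SearchSpace.cube(0.0, 1.0, 4)
        T = rng.random((5, 4))
        np.testing.assert_array_equal(boundary_control(T, space, rng), T)

    def test_selection_rules(self, rng):
        P = rng.random((5, 2))
        T = rng.random((5, 2))
        fitP = np.ones(5)
        # all trials worse -> parents kept
        P2, f2 = greedy_selection(P, fitP, T, fitP + 1.0)
        np.testing.assert_array_equal(P2, P)
        # all trials better (and ties accept) -> trials kept
        P3, f3 = greedy_selection(P, fitP, T, fitP)
        np.testing.assert_array_equal(P3, T)
        # elitism
        fitT = rng.random(5)
        _, f4 = greedy_selection(P, fitP, T, fitT)
        assert f4.min() <= fitP.min()


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def _sphere_spec(D=2, half_width=5.0):
    return ObjectiveSpec(evaluate=lambda x: float((np.asarray(x) ** 2).sum()),
                         space=SearchSpace.cube(-half_width, half_width, D),
                         name="sphere")


class TestOptimize:
    def test_sphere_converges(self):
        pop, trace = optimize(_sphere_spec(),
                              OptimizerConfig(N=20, epochs=200, seed=0))
        assert pop.best_sol <= 1e-8
        assert pop.best_sol == trace.best_per_iteration[-1]

    @pytest.mark.parametrize("algorithm", ["nvsa", "bsd"])
    def test_trace_monotone_and_feasible(self, algorithm):
        spec = _sphere_spec(D=3)
        pop, trace = optimize(spec, OptimizerConfig(
            N=10, epochs=50, algorithm=algorithm, seed=5))
        t = trace.best_per_iteration
        assert np.all(np.diff(t) <= 0.0)
        assert spec.space.contains(pop.P)
        assert spec.space.contains(pop.best_PV)

    def test_evaluation_accounting(self):
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            return float((np.asarray(x) ** 2).sum())

        spec = ObjectiveSpec(evaluate=f, space=SearchSpace.cube(-1, 1, 2))
        _, trace = optimize(spec, OptimizerConfig(N=8, epochs=1, seed=1))
        assert calls["n"] == 16 == trace.evaluations  # exactly 2N for 1 epoch
        calls["n"] = 0
        _, trace = optimize(spec, OptimizerConfig(N=8, epochs=13, seed=1))
        assert calls["n"] == 8 * 14 == trace.evaluations

    @pytest.mark.parametrize("algorithm", ["nvsa", "bsd"])
    def test_seed_determinism_bitwise(self, algorithm):
        cfg = OptimizerConfig(N=12, epochs=40, algorithm=algorithm, seed=99)
        p1, t1 = optimize(_sphere_spec(), cfg)
        p2, t2 = optimize(_sphere_spec(), cfg)
        assert p1.best_sol == p2.best_sol
        np.testing.assert_array_equal(t1.best_per_iteration,
                                      t2.best_per_iteration)
        np.testing.assert_array_equal(p1.P, p2.P)

    def test_maximize_by_negation(self):
        spec = ObjectiveSpec(
            evaluate=lambda x: -float((np.asarray(x) ** 2).sum()),
            space=SearchSpace.cube(-2, 2, 2), name="neg-sphere")
        pop, _ = optimize(spec, OptimizerConfig(
            N=15, epochs=100, seed=2, sense="maximize"))
        # internal scale is minimisation of the negated objective
        assert pop.best_sol <= 1e-6
        assert np.all(np.abs(pop.best_PV) < 1e-2)

    def test_non_finite_fitness_becomes_inf(self):
        def f(x):
            return np.nan if x[0] > 0 else float(x[0] ** 2)

        spec = ObjectiveSpec(evaluate=f, space=SearchSpace.cube(-1, 1, 1))
        with pytest.warns(RuntimeWarning, match="non-finite"):
            pop, _ = optimize(spec, OptimizerConfig(N=10, epochs=5, seed=3))
        assert np.isfinite(pop.best_sol)
        assert pop.best_PV[0] <= 0

    def test_x0_injection(self):
        spec = _sphere_spec()
        x0 = np.array([0.5, -0.5])
        with pytest.raises(ValueError):
            optimize(spec, OptimizerConfig(N=5, epochs=1, seed=0),
                     x0=np.array([9.0, 0.0]))
        pop, _ = optimize(spec, OptimizerConfig(N=5, epochs=1, seed=0), x0=x0)
        assert pop.best_sol <= float((x0 ** 2).sum())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(N=3)
        with pytest.raises(ValueError):
            OptimizerConfig(epochs=0)
        with pytest.raises(ValueError):
            OptimizerConfig(algorithm="pso")

    def test_config_file_roundtrip(self, tmp_path):
        from nvsa.optimizers import load_config

        path = tmp_path / "cfg.yaml"
        path.write_text("algorithm: bsd\nN: 25\nepochs: 300\nseed: 4\n"
                        "vibration: {a: 500, b: 2000, c: 2, d: 4}\n")
        cfg = load_config(path)
        assert cfg.algorithm == "bsd" and cfg.N == 25 and cfg.epochs == 300
        assert cfg.vibration.a == 500 and cfg.vibration.d == 4

    def test_trace_csv_export(self, tmp_path):
        import pandas as pd

        _, trace = optimize(_sphere_spec(), OptimizerConfig(
            N=8, epochs=10, seed=0))
        out = tmp_path / "trace.csv"
        trace.to_csv(out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["iteration", "best_value"]
        assert len(df) == 10
        np.testing.assert_allclose(df["best_value"].values,
                                   trace.best_per_iteration)
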