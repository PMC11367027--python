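import math

import numpy as np
import pytest

from ecglearn import dfa
from ecglearn.dfa import (Dragonfly, HyperparamSpec, Swarm,
                          classifier_error_rate, compute_behaviors,
                          default_ssae_spec, dfa_optimize, tune_ssae,
                          update_swarm)


def _swarm(positions, steps=None, bounds=((-5, 5), (-5, 5)), radius=10.0,
           food=None, enemy=None, T=10, seed=0):
    positions = [np.asarray(p, float) for p in positions]
    d = positions[0].size
    steps = steps or [np.zeros(d) for _ in positions]
    members = [Dragonfly(position=p, step=np.asarray(s, float))
               for p, s in zip(positions, steps)]
    sw = Swarm(members=members, bounds=np.asarray(bounds, float), T=T,
               rng=np.random.default_rng(seed))
    sw.radius = np.full(d, radius)
    sw.food = np.zeros(d) if food is None else np.asarray(food, float)
    sw.enemy = np.ones(d) if enemy is None else np.asarray(enemy, float)
    return sw


class TestBehaviors:
    def test_member_at_food_has_zero_food_vector(self):
        sw = _swarm([[1.0, 2.0], [0.0, 0.0]], food=[1.0, 2.0])
        _, _, _, F, _ = compute_behaviors(sw, 0)
        np.testing.assert_array_equal(F, 0.0)

    def test_hand_evaluated_single_neighbor(self):
        """X=[1,0], neighbor at origin with speed [0.5,0]."""
        sw = _swarm([[1.0, 0.0], [0.0, 0.0]], steps=[[0, 0], [0.5, 0.0]])
        S, A, C, _, _ = compute_behaviors(sw, 0)
        np.testing.assert_allclose(S, [-1.0, 0.0])
        np.testing.assert_allclose(A, [0.5, 0.0])
        np.testing.assert_allclose(C, [-1.0, 0.0])

    def test_symmetric_neighbors_cancel_cohesion(self):
        sw = _swarm([[0.0, 0.0], [1.0, 1.0], [-1.0, -1.0]])
        _, _, C, _, _ = compute_behaviors(sw, 0)
        np.testing.assert_allclose(C, 0.0, atol=1e-12)

    def test_no_neighbors_fallback_values(self):
        sw = _swarm([[0.0, 0.0], [4.0, 4.0]], steps=[[0.3, -0.2], [0, 0]],
                    radius=0.5)
        S, A, C, _, _ = compute_behaviors(sw, 0)
        np.testing.assert_array_equal(S, 0.0)
        np.testing.assert_allclose(A, [0.3, -0.2])
        np.testing.assert_array_equal(C, 0.0)

    def test_matches_brute_force_on_random_swarms(self):
        """Behavior vectors equal a direct re-evaluation of the definitions
        on random 5-member swarms (exact)."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            pos = rng.uniform(-3, 3, size=(5, 3))
            vel = rng.normal(size=(5, 3))
            sw = _swarm(list(pos), steps=list(vel),
                        bounds=[(-5, 5)] * 3, radius=2.5,
                        food=rng.uniform(-3, 3, 3), enemy=rng.uniform(-3, 3, 3))
            for i in range(5):
                nbr = [j for j in range(5) if j != i
                       and np.all(np.abs(pos[j] - pos[i]) <= 2.5)]
                S, A, C, F, E = compute_behaviors(sw, i)
                if nbr:
                    np.testing.assert_array_equal(
                        S, -sum(pos[i] - pos[j] for j in nbr))
                    np.testing.assert_allclose(
                        A, sum(vel[j] for j in nbr) / len(nbr))
                    np.testing.assert_allclose(
                        C, sum(pos[j] for j in nbr) / len(nbr) - pos[i])
                else:
                    np.testing.assert_array_equal(S, 0)
                    np.testing.assert_array_equal(A, vel[i])
                    np.testing.assert_array_equal(C, 0)
                np.testing.assert_array_equal(F, sw.food - pos[i])
                np.testing.assert_array_equal(E, sw.enemy + pos[i])


class TestUpdateSwarm:
    def test_pure_food_attraction_moves_to_food(self):
        """With only f=1, w=0 active, a member's step equals X+ - X."""
        sw = _swarm([[2.0, 2.0], [1.0, 1.0]], food=[0.0, 0.0],
                    enemy=[4.0, 4.0], radius=10.0, T=1000)
        sw.t = 0

        def fake_schedules(s):
            s.coefficients = (0.0, 0.0, 0.0, 1.0, 0.0)
            s.w = 0.0

        original = dfa._advance_schedules
        dfa._advance_schedules = lambda s: fake_schedules(s)
        try:
            update_swarm(sw, lambda x: float(np.sum(x ** 2)))
        finally:
            dfa._advance_schedules = original
        np.testing.assert_allclose(sw.members[0].position, [0.0, 0.0])
        np.testing.assert_allclose(sw.members[1].position, [0.0, 0.0])

    def test_isolated_members_take_levy_flight(self):
        sw = _swarm([[1.0, 1.0], [-4.0, -4.0]], radius=0.01)
        before = [m.position.copy() for m in sw.members]
        # freeze radius so members stay isolated during this single update
        original = dfa._advance_schedules

        def fake(s):
            original(s)
            s.radius = np.full(2, 0.01)

        dfa._advance_schedules = fake
        try:
            update_swarm(sw, lambda x: float(np.sum(x ** 2)))
        finally:
            dfa._advance_schedules = original
        for m, b in zip(sw.members, before):
            assert not np.array_equal(m.position, b)
            np.testing.assert_array_equal(m.step, 0.0)

    def test_positions_stay_inside_bounds(self):
        bounds = [(-1, 1), (-1, 1)]
        best, _, _ = dfa_optimize(lambda x: -float(np.sum(x ** 2)), bounds,
                                  pop_size=8, iterations=20, seed=3)
        assert np.all(best >= -1) and np.all(best <= 1)

    def test_food_fitness_never_increases(self):
        rng = np.random.default_rng(0)
        _, _, hist = dfa_optimize(lambda x: float(rng.normal()),
                                  [(-2, 2)] * 3, pop_size=6, iterations=30,
                                  seed=5)
        bests = [h["best_fitness"] for h in hist]
        assert all(b <= a + 1e-12 for a, b in zip(bests, bests[1:]))

    def test_non_finite_fitness_treated_as_worst(self):
        def fitness(x):
            return math.nan if x[0] > 0 else float(np.sum(x ** 2))

        best, bf, _ = dfa_optimize(fitness, [(-1, 1)], pop_size=6,
                                   iterations=10, seed=2)
        assert math.isfinite(bf)


class TestOptimize:
    def test_sphere_converges(self):
        best, bf, hist = dfa_optimize(lambda x: float(np.sum(x ** 2)),
                                      [(-5, 5), (-5, 5)], pop_size=20,
                                      iterations=100, seed=1)
        assert bf < 0.1
        assert bf < hist[0]["best_fitness"] or bf < 25.0

    def test_single_iteration_history_length(self):
        _, _, hist = dfa_optimize(lambda x: float(np.sum(x ** 2)),
                                  [(-1, 1)], pop_size=4, iterations=1, seed=0)
        assert len(hist) == 1

    def test_constant_fitness_keeps_flat_history(self):
        _, bf, hist = dfa_optimize(lambda x: 7.0, [(-1, 1)] * 2,
                                   pop_size=5, iterations=10, seed=0)
        assert bf == 7.0
        assert all(h["best_fitness"] == 7.0 for h in hist)

    def test_seeded_determinism(self):
        f = lambda x: float(np.sum(np.abs(x)))
        a = dfa_optimize(f, [(-3, 3)] * 2, pop_size=8, iterations=15, seed=9)
        b = dfa_optimize(f, [(-3, 3)] * 2, pop_size=8, iterations=15, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1] and a[2] == b[2]

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            dfa_optimize(lambda x: 0.0, [(-1, 1)], pop_size=1, iterations=1)


class TestHyperparamSpec:
    def test_log_dimensions_decode_from_log10_space(self):
        spec = default_ssae_spec()
        internal = spec.internal_bounds()
        lo = spec.decode(internal[:, 0])
        hi = spec.decode(internal[:, 1])
        assert lo["size1"] == 16 and hi["size1"] == 128
        assert lo["rho"] == pytest.approx(0.01)
        assert hi["beta"] == pytest.approx(10.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            HyperparamSpec(names=("a",), bounds=((1.0, 1.0),),
                           scales=("linear",), integers=(False,))


class TestErrorRateFitness:
    def test_perfect_predictions_score_zero(self):
        Y = np.eye(5, dtype=int)
        assert classifier_error_rate(Y, Y) == 0.0

    def test_everything_wrong_scores_hundred(self):
        Y = np.zeros((10, 5), dtype=int)
        assert classifier_error_rate(Y, 1 - Y) == 100.0

    def test_error_rate_arithmetic_at_scale(self):
        """2965 samples with mean per-class 2646 correct -> 10.76%."""
        n, correct = 2965, 2646
        y_true = np.zeros((n, 5), dtype=int)
        y_pred = np.zeros((n, 5), dtype=int)
        y_pred[: n - correct, :] = 1  # same 319 wrong in every class
        assert classifier_error_rate(y_true, y_pred) == pytest.approx(10.76,
                                                                      abs=0.01)

    def test_exact_match_stricter_than_macro(self):
        y_true = np.zeros((4, 2), dtype=int)
        y_pred = np.array([[1, 0], [0, 1], [0, 0], [0, 0]])
        assert classifier_error_rate(y_true, y_pred) == 25.0
        assert classifier_error_rate(y_true, y_pred, exact_match=True) == 50.0

    def test_tune_ssae_returns_decoded_config(self):
        rng = np.random.default_rng(4)
        X = rng.random((40, 8))
        Y = (X[:, :5] > 0.5).astype(int)
        best, fit, hist = tune_ssae(X[:30], Y[:30], X[30:], Y[30:],
                                    pop_size=3, iterations=2, seed=1,
                                    fitness_epochs=1)
        assert set(best) == {"size1", "size2", "rho", "beta", "eta"}
        assert isinstance(best["size1"], int)
        assert 0.0 <= fit <= 100.0
        assert len(hist) == 2
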