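import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwoselect.igwo import (CHAOTIC_MAPS, PackState, Wolf, candidate_position,
                            chaotic_sequence, igwo_minimize, igwo_step,
                            init_pack)

sphere = lambda z: float(np.sum(np.asarray(z) ** 2))  # noqa: E731


class TestChaoticSequence:
    def test_logistic_iterates(self):
        np.testing.assert_allclose(chaotic_sequence("logistic", 0.3, 2),
                                   [0.84, 0.5376])

    def test_fixed_point_rejected(self):
        with pytest.raises(ValueError, match="fixed point"):
            chaotic_sequence("logistic", 0.75, 5)

    def test_x0_out_of_range(self):
        with pytest.raises(ValueError):
            chaotic_sequence("tent", 1.5, 5)

    def test_zero_length(self):
        assert chaotic_sequence("singer", 0.3, 0).size == 0

    @given(st.sampled_from(sorted(CHAOTIC_MAPS)),
           st.floats(0.01, 0.99).filter(
               lambda x: min(abs(x - f) for f in (0, .25, .5, .75, 1)) > 1e-3))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_values_stay_in_unit_interval(self, name, x0):
        seq = chaotic_sequence(name, x0, 50)
        assert np.all(seq > 0) and np.all(seq < 1)


class TestInitPack:
    def test_bounds_and_determinism(self):
        a = init_pack(5, 3, (0, 1), sphere, seed=9)
        b = init_pack(5, 3, (0, 1), sphere, seed=9)
        assert a.positions.shape == (5, 3)
        assert np.all((a.positions >= 0) & (a.positions <= 1))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_alpha_is_best_wolf(self):
        pack = init_pack(8, 4, (-2, 2), sphere, seed=1)
        best = np.argmin([sphere(p) for p in pack.positions])
        np.testing.assert_array_equal(pack.alpha.position,
                                      pack.positions[best])
        assert pack.alpha.fitness <= pack.beta.fitness <= pack.delta.fitness

    def test_too_few_wolves(self):
        with pytest.raises(ValueError):
            init_pack(3, 2, (0, 1), sphere)


class TestCandidatePosition:
    def leaders_at(self, *pts):
        return tuple(Wolf(np.asarray(p, dtype=float), 0.0) for p in pts)

    def test_a_zero_gives_leader_centroid(self):
        leaders = self.leaders_at([0, 0], [3, 0], [0, 3])
        rng = np.random.default_rng(0)
        cand = candidate_position(np.array([9.0, -9.0]), leaders, 0.0, rng)
        np.testing.assert_allclose(cand, [1.0, 1.0])

    def test_coincident_pack_is_stationary(self):
        p = np.array([1.5, -2.0])
        leaders = self.leaders_at(p, p, p)
        cand = candidate_position(p.copy(), leaders, 0.0,
                                  np.random.default_rng(4))
        np.testing.assert_allclose(cand, p)

    def test_matches_hand_evaluated_update(self):
        """Replay the rng stream and evaluate the leader-guided update."""
        leaders = self.leaders_at([1.0, 2.0], [-1.0, 0.5], [0.0, -2.0])
        z = np.array([0.3, -0.7])
        a = 1.2
        cand = candidate_position(z.copy(), leaders, a,
                                  np.random.default_rng(123))
        rng = np.random.default_rng(123)
        acc = np.zeros(2)
        for ldr in leaders:
            r1, r2 = rng.random(2), rng.random(2)
            B = 2 * a * r1 - a
            E = 2 * r2
            D = np.abs(E * ldr.position - z)
            acc += ldr.position - B * D
        np.testing.assert_allclose(cand, acc / 3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            candidate_position(np.zeros(2), self.leaders_at([1.0], [1.0], [1.0]),
                               1.0, np.random.default_rng(0))


class TestIgwoStep:
    def test_constant_fitness_keeps_global_best(self):
        fn = lambda z: 1.0  # noqa: E731
        pack = init_pack(6, 2, (0, 1), fn, seed=0, max_iter=10)
        rng = np.random.default_rng(0)
        for _ in range(10):
            igwo_step(pack, fn, rng)
        assert pack.best_fitness == 1.0

    def test_leader_ordering_after_steps(self):
        pack = init_pack(10, 3, (-5, 5), sphere, seed=2, max_iter=50)
        rng = np.random.default_rng(2)
        for _ in range(50):
            igwo_step(pack, sphere, rng)
            assert pack.alpha.fitness <= pack.beta.fitness
            assert pack.beta.fitness <= pack.delta.fitness
            assert pack.delta.fitness <= np.max(pack.fitnesses)
            assert pack.best_fitness <= pack.alpha.fitness + 1e-15

    def test_a_decays_linearly(self):
        pack = init_pack(4, 1, (0, 1), sphere, seed=0, max_iter=4)
        expected = [1.5, 1.0, 0.5, 0.0]
        rng = np.random.default_rng(0)
        for e in expected:
            igwo_step(pack, sphere, rng)
            assert pack.a == pytest.approx(e)

    def test_non_finite_fitness_errors(self):
        pack = init_pack(5, 1, (0, 1), sphere, seed=0, max_iter=5)
        with pytest.raises(ValueError, match="non-finite"):
            igwo_step(pack, lambda z: float("nan"), np.random.default_rng(0))


class TestIgwoMinimize:
    def test_parabola_1d(self):
        pos, fit, _ = igwo_minimize(lambda z: (z[0] - 3.0) ** 2, dim=1,
                                    bounds=(0, 10), n_wolves=20, max_iter=100,
                                    seed=5)
        assert abs(pos[0] - 3.0) < 0.1

    def test_boundary_optimum(self):
        pos, _, _ = igwo_minimize(lambda z: float(z[0]), dim=1, bounds=(0, 10),
                                  n_wolves=20, max_iter=100, seed=1)
        assert pos[0] < 0.05

    def test_trace_monotone_and_deterministic(self):
        _, f1, t1 = igwo_minimize(sphere, dim=3, bounds=(-5, 5), seed=8,
                                  n_wolves=12, max_iter=40)
        _, f2, t2 = igwo_minimize(sphere, dim=3, bounds=(-5, 5), seed=8,
                                  n_wolves=12, max_iter=40)
        assert np.all(np.diff(t1) <= 0) and t1[-1] == f1
        np.testing.assert_array_equal(t1, t2)
        assert f1 == f2
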