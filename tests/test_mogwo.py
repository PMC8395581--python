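"""Grey wolf optimizer: dominance, archive, leaders, position updates."""

import numpy as np
import pytest

from lmdcsp.mogwo import (
    MOGWOConfig,
    ObjectiveVector,
    ParetoArchive,
    choose_solution,
    dominates,
    evaluate_objectives,
    optimize_objective,
    update_positions,
)


class TestObjectiveVector:
    @pytest.mark.parametrize(
        "nc,ne,cr,accuracy",
        [
            ((20, 16, 16), (0, 4, 4), (1.00, 0.80, 0.80), 0.8667),
            ((19, 17, 17), (1, 3, 3), (0.95, 0.85, 0.85), 0.8833),
            ((20, 20, 20), (0, 0, 0), (1.0, 1.0, 1.0), 1.0),
        ],
    )
    def test_per_class_rates_and_mean_accuracy(self, nc, ne, cr, accuracy):
        obj = ObjectiveVector.from_counts(nc, ne)
        assert obj.cr == pytest.approx(cr, abs=1e-12)
        assert round(obj.accuracy, 4) == accuracy

    def test_accuracy_is_exact_count_ratio(self, rng):
        for _ in range(20):
            nc = rng.integers(1, 30, size=3)
            ne = rng.integers(0, 30, size=3)
            obj = ObjectiveVector.from_counts(nc, ne)
            assert obj.accuracy == nc.sum() / (nc.sum() + ne.sum())


class TestDominance:
    def test_componentwise_better(self):
        assert dominates((0.9, 0.9, 0.9, 0.9), (0.8, 0.9, 0.9, 0.9))

    def test_equal_vectors_do_not_dominate(self):
        assert not dominates((0.5, 0.5), (0.5, 0.5))

    def test_tradeoff_is_mutually_non_dominated(self):
        u, v = (0.9, 0.5, 0.7, 0.7), (0.8, 0.6, 0.7, 0.7)
        assert not dominates(u, v) and not dominates(v, u)


class TestArchive:
    def _archive(self, size=10):
        return ParetoArchive(MOGWOConfig(archive_size=size, seed=0))

    def test_insert_into_empty(self, rng):
        a = self._archive()
        assert a.update(np.zeros(3), np.array([0.5, 0.5]), rng)
        assert len(a) == 1

    def test_dominated_candidate_rejected(self, rng):
        a = self._archive()
        a.update(np.zeros(3), np.array([0.9, 0.9]), rng)
        assert not a.update(np.ones(3), np.array([0.8, 0.8]), rng)
        assert len(a) == 1

    def test_candidate_purges_dominated_members(self, rng):
        a = self._archive()
        a.update(np.zeros(3), np.array([0.5, 0.5]), rng)
        a.update(np.ones(3), np.array([0.4, 0.9]), rng)
        a.update(2 * np.ones(3), np.array([0.95, 0.95]), rng)
        assert len(a) == 1
        assert np.allclose(a.members[0].values, [0.95, 0.95])

    def test_stream_stays_pairwise_non_dominated_and_bounded(self, rng):
        a = self._archive(size=10)
        for _ in range(200):
            a.update(rng.random(3), rng.random(4), rng)
            vals = [m.values for m in a.members]
            for i in range(len(vals)):
                for j in range(len(vals)):
                    if i != j:
                        assert not dominates(vals[i], vals[j])
            assert len(a) <= 10

    def test_leaders_of_three_member_archive_are_all_members(self, rng):
        a = self._archive()
        fronts = [np.array([0.9, 0.1]), np.array([0.5, 0.5]), np.array([0.1, 0.9])]
        for k, f in enumerate(fronts):
            a.update(np.full(3, float(k)), f, rng)
        leaders = a.select_leaders(rng)
        picked = sorted(float(l.position[0]) for l in leaders)
        assert picked == [0.0, 1.0, 2.0]

    def test_single_member_archive_repeats_leader(self, rng):
        a = self._archive()
        a.update(np.zeros(3), np.array([0.5, 0.5]), rng)
        leaders = a.select_leaders(rng)
        assert all(np.array_equal(l.position, np.zeros(3)) for l in leaders)

    def test_sparse_cell_preferred_by_roulette(self, rng):
        """With occupancies 1 vs 9 and pressure 4, the sparse cell should be
        chosen almost always (weight ratio 9^4)."""
        cfg = MOGWOConfig(archive_size=10, leader_selection_pressure=4, seed=0)
        a = ParetoArchive(cfg)
        # build a two-cell configuration on a 2-objective trade-off: a tight
        # cluster of 9 and one far-away solitary member
        for k in range(9):
            a.update(np.full(3, float(k)), np.array([0.90 + 0.001 * k, 0.20 - 0.001 * k]), rng)
        a.update(np.full(3, 99.0), np.array([0.10, 0.90]), rng)
        counts = a.cell_counts()
        assert sorted(counts.values()) == [1, 9]
        hits = 0
        n_draws = 10_000
        for _ in range(n_draws):
            alpha = a.select_leaders(rng)[0]
            hits += float(alpha.position[0]) == 99.0
        assert hits / n_draws > 0.9


class TestUpdatePositions:
    def test_zero_a_collapses_onto_common_leader(self, rng):
        cfg = MOGWOConfig(seed=0)
        target = np.array([1.0, 2.0, 3.0])
        wolves = rng.random((8, 3)) * 8
        bounds = np.array([[0.0, 8.0]] * 3)
        new = update_positions(wolves, [target] * 3, t=cfg.max_iterations, config=cfg, rng=rng, bounds=bounds)
        assert np.allclose(new, target, atol=1e-12)

    def test_hand_computed_single_wolf_step(self):
        """Arithmetic oracle with stubbed r1 = r2 = 0.25 at t = 0 (a = 2)."""

        class StubRNG:
            def random(self, shape):
                return np.full(shape, 0.25)

        cfg = MOGWOConfig(max_iterations=100, seed=0)
        X = np.array([[1.0, 1.0, 1.0]])
        leaders = [np.array([2.0, 2.0, 2.0]), np.array([0.0, 0.0, 0.0]), np.array([4.0, 4.0, 4.0])]
        bounds = np.array([[-100.0, 100.0]] * 3)
        # a = 2, A = 2*2*0.25 - 2 = -1, C = 0.5
        # leader 2: D = |0.5*2 - 1| = 0 -> cand = 2 - (-1)*0   = 2
        # leader 0: D = |0 - 1|     = 1 -> cand = 0 - (-1)*1   = 1
        # leader 4: D = |2 - 1|     = 1 -> cand = 4 - (-1)*1   = 5
        expected = (2.0 + 1.0 + 5.0) / 3.0
        new = update_positions(X, leaders, t=0, config=cfg, rng=StubRNG(), bounds=bounds)
        assert np.allclose(new, expected, atol=1e-12)

    def test_positions_stay_in_bounds(self, rng):
        cfg = MOGWOConfig(seed=0)
        bounds = np.array([[0.01, 8.0], [0.01, 8.0], [0.001, 8.0]])
        wolves = bounds[:, 0] + rng.random((12, 3)) * (bounds[:, 1] - bounds[:, 0])
        leaders = [rng.random(3) * 8 for _ in range(3)]
        for t in range(0, 100, 10):
            wolves = update_positions(wolves, leaders, t, cfg, rng, bounds)
            assert np.all(wolves >= bounds[:, 0]) and np.all(wolves <= bounds[:, 1])


class TestOptimize:
    @staticmethod
    def _surrogate(p):
        """Bi-objective with a closed-form Pareto set: the segment x2 = 0,
        x1 in [0, 1]; front {(-t^2, -(1-t)^2) : t in [0, 1]}."""
        x1, x2 = p
        return np.array([-(x1**2 + x2**2), -((x1 - 1) ** 2 + x2**2)])

    def test_recovers_closed_form_front(self):
        cfg = MOGWOConfig(n_wolves=10, max_iterations=50, archive_size=10, seed=3)
        bounds = np.array([[-1.0, 2.0], [-1.0, 2.0]])
        archive, _ = optimize_objective(self._surrogate, bounds, cfg)
        assert len(archive) >= 3
        for m in archive.members:
            x1, x2 = m.position
            dist = abs(x2) + max(0.0, -x1) + max(0.0, x1 - 1.0)
            assert dist < 0.05

    def test_deterministic_under_seed(self):
        cfg = MOGWOConfig(n_wolves=6, max_iterations=20, seed=11)
        bounds = np.array([[-1.0, 2.0], [-1.0, 2.0]])
        a1, c1 = optimize_objective(self._surrogate, bounds, cfg)
        a2, c2 = optimize_objective(self._surrogate, bounds, cfg)
        assert len(a1) == len(a2)
        for m1, m2 in zip(a1.members, a2.members):
            assert np.array_equal(m1.position, m2.position)
        assert np.array_equal(c1.position, c2.position)

    def test_choose_solution_prefers_accuracy_then_worst_class(self):
        cfg = MOGWOConfig(seed=0)
        a = ParetoArchive(cfg)
        rng = np.random.default_rng(0)
        a.update(np.array([1.0, 1, 1]), ObjectiveVector.from_counts((19, 17, 17), (1, 3, 3)), rng)
        a.update(np.array([2.0, 2, 2]), ObjectiveVector.from_counts((20, 16, 17), (0, 4, 3)), rng)
        chosen = choose_solution(a)
        # equal accuracy 53/60: tie broken by larger min per-class rate
        assert np.array_equal(chosen.position, [1.0, 1, 1])


class TestEvaluateObjectives:
    def test_separable_features_reach_perfect_objectives(self, rng):
        X = np.vstack(
            [rng.standard_normal((10, 2)) * 0.3 + c for c in ((0, 0), (6, 0), (0, 6))]
        )
        y = np.repeat(["a", "e", "f"], 10)
        obj = evaluate_objectives(np.array([1.0, 1.0, 2.0]), X, y, folds=5, seed=0)
        assert obj.accuracy == 1.0 and obj.cr == (1.0, 1.0, 1.0)

    def test_missing_class_in_folds_rejected(self, rng):
        X = rng.standard_normal((7, 2))
        y = np.array(["a", "a", "a", "a", "a", "a", "e"])
        with pytest.raises(Exception):
            evaluate_objectives(np.array([1.0, 1.0, 1.0]), X, y, folds=5, seed=0)
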