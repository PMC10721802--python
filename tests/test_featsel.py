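"""Wrapper feature-selection tests.

The exhaustive oracle over all nonempty masks is the independent reference
for the metaheuristics; the combined-objective worked example is evaluated
directly from its closed form.
"""

import numpy as np
import pytest

from mcifmri import (
    ObjectiveSpec,
    SearchBudget,
    combined_objective,
    evaluate_mask,
    exhaustive_best_subset,
    run_feature_selection,
)
from mcifmri.featsel import METHODS
from tests.conftest import make_table

SMALL_BUDGET = SearchBudget(population_size=10, n_iterations=8, sa_steps=60,
                            sffs_max_features=5, init_density=0.2)


class TestCombinedObjective:
    def test_perfect_classifier_empty_mask_is_zero(self):
        for alpha in (0.0, 0.5, 0.9, 1.0):
            assert combined_objective(1.0, 0, 100, alpha) == 0.0

    def test_alpha_one_drops_feature_term(self):
        assert combined_objective(0.8, 50, 100, alpha=1.0) == pytest.approx(0.2)

    def test_worked_example(self):
        # 0.9 * 0.15 + 0.1 * 40/396
        assert combined_objective(0.85, 40, 396, alpha=0.9) == pytest.approx(
            0.9 * 0.15 + 0.1 * 40 / 396, abs=1e-12
        )

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            combined_objective(0.5, 1, 2, alpha=1.5)


class TestEvaluateMask:
    def test_perfect_feature_scores_one(self):
        table = make_table(n_per_class=20, n_features=5, seed=0)
        table.data.iloc[:, 2] = table.y * 10.0 - 5.0
        mask = np.zeros(5, dtype=bool)
        mask[2] = True
        fv = evaluate_mask(mask, table, spec=ObjectiveSpec(alpha=0.9, seed=1))
        assert fv.p == 1.0
        assert fv.f == pytest.approx(0.1 * 1 / 5)

    def test_null_table_scores_near_chance(self):
        ps = []
        for seed in range(20):
            table = make_table(n_per_class=30, n_features=6, seed=200 + seed)
            fv = evaluate_mask(np.ones(6, dtype=bool), table, spec=ObjectiveSpec(seed=seed))
            ps.append(fv.p)
        assert abs(np.mean(ps) - 0.5) <= 0.15

    def test_deterministic_given_seed(self):
        table = make_table(n_per_class=15, n_features=6, planted={1: 1.0}, seed=3)
        mask = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
        spec = ObjectiveSpec(seed=11)
        assert evaluate_mask(mask, table, spec=spec) == evaluate_mask(mask, table, spec=spec)

    def test_empty_mask_rejected(self):
        table = make_table(n_per_class=10, n_features=4)
        with pytest.raises(ValueError, match="empty"):
            evaluate_mask(np.zeros(4, dtype=bool), table)


class TestExhaustiveOracle:
    def test_three_features_evaluate_seven_masks(self):
        table = make_table(n_per_class=10, n_features=3, seed=1)
        res = exhaustive_best_subset(table, ObjectiveSpec(cv_folds=5, seed=0))
        assert res.n_evaluations == 7

    def test_tie_break_prefers_fewer_features(self):
        table = make_table(n_per_class=20, n_features=4, seed=2)
        table.data.iloc[:, 1] = table.y * 8.0
        res = exhaustive_best_subset(table, ObjectiveSpec(cv_folds=5, seed=0))
        assert res.fitness.p == 1.0
        assert res.fitness.n_selected == 1
        assert res.mask[1]

    def test_beats_random_search(self, rng):
        table = make_table(n_per_class=15, n_features=10, planted={0: 1.0, 7: 0.8}, seed=5)
        spec = ObjectiveSpec(cv_folds=5, seed=3)
        oracle = exhaustive_best_subset(table, spec)
        best_random = -np.inf
        for _ in range(200):
            mask = rng.random(10) < 0.5
            if not mask.any():
                continue
            best_random = max(best_random, evaluate_mask(mask, table, spec=spec).p)
        assert oracle.fitness.p >= best_random

    def test_refuses_large_tables(self):
        table = make_table(n_per_class=5, n_features=25, seed=0)
        with pytest.raises(ValueError, match="max_features"):
            exhaustive_best_subset(table, max_features=20)


class TestSelectors:
    @pytest.mark.parametrize("method", METHODS)
    def test_dominant_feature_is_found_by_every_method(self, method):
        table = make_table(n_per_class=20, n_features=11, seed=0)
        table.data.iloc[:, 4] = table.y * 6.0 - 3.0
        res = run_feature_selection(method, table, ObjectiveSpec(seed=42), SMALL_BUDGET)
        assert bool(res.mask[4])
        assert res.fitness.p == 1.0

    @pytest.mark.parametrize("method", METHODS)
    def test_trace_is_monotone_best_so_far(self, method):
        table = make_table(n_per_class=12, n_features=8, planted={2: 1.2}, seed=7)
        res = run_feature_selection(method, table, ObjectiveSpec(cv_folds=5, seed=5), SMALL_BUDGET)
        trace = np.asarray(res.trace)
        if method in ("PSO", "NSGA2"):  # minimized combined objective
            assert np.all(np.diff(trace) <= 1e-12)
        else:  # maximized accuracy
            assert np.all(np.diff(trace) >= -1e-12)

    def test_ga_is_reproducible(self):
        table = make_table(n_per_class=12, n_features=8, planted={0: 1.5}, seed=2)
        spec = ObjectiveSpec(cv_folds=5, seed=8)
        a = run_feature_selection("GA", table, spec, SMALL_BUDGET)
        b = run_feature_selection("GA", table, spec, SMALL_BUDGET)
        assert np.array_equal(a.mask, b.mask)
        assert a.trace == b.trace

    def test_nsga2_front_is_nondominated(self):
        table = make_table(n_per_class=15, n_features=10, planted={1: 2.0, 6: 1.0}, seed=4)
        res = run_feature_selection("NSGA2", table, ObjectiveSpec(cv_folds=5, seed=6), SMALL_BUDGET)
        front = [(int(o[0]), float(o[1])) for _, o in res.front]
        assert len(front) <= SMALL_BUDGET.population_size
        for i, a in enumerate(front):
            for j, b in enumerate(front):
                if i != j:
                    assert not (a[0] <= b[0] and a[1] <= b[1] and a != b)

    def test_sffs_reaches_exhaustive_optimum_on_separable_toy(self):
        table = make_table(n_per_class=15, n_features=10, seed=9)
        for col in (1, 4, 8):
            table.data.iloc[:, col] = table.y * 4.0 + np.asarray(table.data.iloc[:, col])
        spec = ObjectiveSpec(cv_folds=5, seed=2)
        oracle = exhaustive_best_subset(table, spec)
        res = run_feature_selection("SFFS", table, spec, SearchBudget())
        assert res.fitness.p >= oracle.fitness.p - 0.02

    def test_unknown_method_rejected(self):
        table = make_table(n_per_class=10, n_features=4)
        with pytest.raises(ValueError, match="unknown method"):
            run_feature_selection("TABU", table)
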