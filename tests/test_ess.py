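import numpy as np
import pytest

from globopt.ess import ESS, ESSOptions, combine_pair, ess_solve, go_beyond
from globopt.problem import EvaluationCounter, OptimizationProblem, Solution, evaluate
from tests.conftest import rosenbrock, sphere


def make_solution(problem, x, counter=None):
    return evaluate(problem, np.asarray(x, float), counter or EvaluationCounter())


class TestCombinePair:
    def test_offspring_inside_unstretched_hyperrectangle(self, sphere_problem, rng):
        p = OptimizationProblem(sphere, np.zeros(2), np.ones(2))
        kids = combine_pair(np.zeros(2), 1.0, np.ones(2), 2.0, p, rng, margin=0.0)
        for k in kids:
            assert np.all(k >= 0.0) and np.all(k <= 1.0)

    def test_integer_coordinate_rounded_within_span(self, rng):
        p = OptimizationProblem(sphere, np.zeros(1), np.full(1, 10.0), integer_indices={0})
        for _ in range(30):
            kids = combine_pair(np.array([2.0]), 0.0, np.array([5.0]), 1.0, p, rng,
                                margin=0.0)
            for k in kids:
                assert k[0] in (2.0, 3.0, 4.0, 5.0)

    def test_identical_parents_never_duplicated(self, rng):
        p = OptimizationProblem(sphere, np.zeros(2), np.ones(2))
        kids = combine_pair(np.full(2, 1.0), 1.0, np.full(2, 1.0), 1.0, p, rng)
        for k in kids:
            assert not np.array_equal(k, np.full(2, 1.0))

    def test_stretch_extends_toward_better_parent(self, rng):
        p = OptimizationProblem(sphere, np.full(1, -10.0), np.full(1, 10.0))
        kids = [
            combine_pair(np.array([0.0]), 0.0, np.array([2.0]), 5.0, p, rng,
                         n_offspring=1, margin=0.5)[0]
            for _ in range(300)
        ]
        lo = min(k[0] for k in kids)
        hi = max(k[0] for k in kids)
        assert lo < -0.2          # box stretched past the better parent at 0
        assert hi <= 2.0 + 1e-12  # but not past the worse parent


class TestOnePlusOneReplacement:
    def _refset(self, problem):
        solver = ESS(problem, ESSOptions(N=4, max_evaluations=100, seed=0))
        solver.refset = [make_solution(problem, [v]) for v in (1.0, 2.0, 3.0, 4.0)]
        solver.stagnation = np.zeros(4, dtype=int)
        solver._initialized = True
        return solver

    def test_offspring_replaces_only_its_own_parent(self, sphere_problem):
        problem = OptimizationProblem(sphere, np.full(1, -10.0), np.full(1, 10.0))
        solver = self._refset(problem)
        before = [s.x[0] for s in solver.refset]
        # better than member 3 but offspring of member 3 specifically
        offspring = make_solution(problem, [0.5])
        assert solver.replace_member(3, offspring)
        after = [s.x[0] for s in solver.refset]
        assert after[3] == 0.5
        assert after[:3] == before[:3]

    def test_worse_offspring_leaves_refset_unchanged(self):
        problem = OptimizationProblem(sphere, np.full(1, -10.0), np.full(1, 10.0))
        solver = self._refset(problem)
        offspring = make_solution(problem, [9.0])
        assert not solver.replace_member(0, offspring)
        assert solver.refset[0].x[0] == 1.0

    def test_offspring_beating_other_member_but_not_parent_changes_nothing(self):
        # f = x^2: offspring at 2.5 beats members at 3 and 4, but its parent is at 1
        problem = OptimizationProblem(sphere, np.full(1, -10.0), np.full(1, 10.0))
        solver = self._refset(problem)
        offspring = make_solution(problem, [2.5])
        assert not solver.replace_member(0, offspring)
        assert [s.x[0] for s in solver.refset] == [1.0, 2.0, 3.0, 4.0]


class TestGoBeyond:
    def test_probes_past_offspring_and_improves(self):
        problem = OptimizationProblem(sphere, np.full(1, -10.0), np.full(1, 10.0))
        counter = EvaluationCounter()
        parent = make_solution(problem, [8.0])
        offspring = make_solution(problem, [6.0])
        best = go_beyond(parent, offspring, problem, counter)
        assert best.penalized < 36.0
        assert best.x[0] < 6.0
        assert counter.count > 0

    def test_non_improving_offspring_returned_untouched(self):
        problem = OptimizationProblem(sphere, np.full(1, -10.0), np.full(1, 10.0))
        counter = EvaluationCounter()
        parent = make_solution(problem, [1.0])
        offspring = make_solution(problem, [5.0])
        out = go_beyond(parent, offspring, problem, counter)
        assert out is offspring
        assert counter.count == 0

    def test_doubling_extrapolation_on_sphere(self):
        # parent (4,4), offspring (3,3): probes (2,2) then (0,0) then (-4,-4);
        # the last worsens, so (0,0) is returned — both coordinates < 3
        problem = OptimizationProblem(sphere, np.full(2, -10.0), np.full(2, 10.0))
        counter = EvaluationCounter()
        parent = make_solution(problem, [4.0, 4.0])
        offspring = make_solution(problem, [3.0, 3.0])
        best = go_beyond(parent, offspring, problem, counter)
        assert np.all(best.x < 3.0)
        np.testing.assert_allclose(best.x, [0.0, 0.0])


class TestMemoryGuidedLocalSearch:
    def test_empty_archive_selects_best_member(self, sphere_problem):
        problem = sphere_problem(2)
        solver = ESS(problem, ESSOptions(N=4, max_evaluations=5000, seed=1))
        solver.initialize()
        best_member = min(solver.refset, key=lambda s: s.penalized)
        solver._memory_guided_local_search()
        assert len(solver.ls_archive) == 1
        np.testing.assert_array_equal(solver.ls_archive[0][0], best_member.x)
        assert min(s.penalized for s in solver.refset) <= best_member.penalized

    def test_all_members_filtered_means_no_evaluations(self, sphere_problem):
        problem = sphere_problem(2)
        solver = ESS(problem, ESSOptions(N=4, max_evaluations=5000, seed=1))
        solver.initialize()
        solver.ls_archive = [(s.x.copy(), s.x.copy()) for s in solver.refset]
        before = solver.counter.count
        solver._memory_guided_local_search()
        assert solver.counter.count == before

    def test_convex_refinement_reaches_analytic_minimizer(self):
        problem = OptimizationProblem(
            lambda x: float((x[0] - 0.5) ** 2 + 2 * (x[1] + 0.25) ** 2),
            np.full(2, -2.0), np.full(2, 2.0),
        )
        solver = ESS(problem, ESSOptions(N=4, max_evaluations=50000, seed=0))
        solver.initialize()
        start = make_solution(problem, [1.0, 1.0], solver.counter)
        refined = solver._local_refine(start)
        np.testing.assert_allclose(refined.x, [0.5, -0.25], atol=1e-5)
        assert refined.penalized < 1e-6


class TestESSSolve:
    def test_sphere_5d_converges(self, sphere_problem):
        result = ess_solve(sphere_problem(5), ESSOptions(max_evaluations=20000, seed=1))
        assert result.best.penalized <= 1e-6

    def test_rosenbrock_2d_converges(self):
        problem = OptimizationProblem(rosenbrock, np.full(2, -5.0), np.full(2, 10.0))
        result = ess_solve(problem, ESSOptions(max_evaluations=50000, seed=1))
        assert result.best.penalized <= 1e-5

    def test_minlp_recovers_mixed_optimum(self):
        problem = OptimizationProblem(
            lambda x: float((x[0] - 0.3) ** 2 + (x[1] - 2.0) ** 2),
            np.array([-1.0, 0.0]), np.array([1.0, 5.0]), integer_indices={1},
        )
        result = ess_solve(problem, ESSOptions(max_evaluations=5000, seed=3))
        assert result.best.x[1] == 2.0
        assert result.best.x[0] == pytest.approx(0.3, abs=1e-4)
        assert result.best.penalized <= 1e-6

    def test_integer_positions_always_integral(self):
        seen = []

        def watch(x):
            seen.append(x.copy())
            return sphere(x)

        problem = OptimizationProblem(
            watch, np.array([-5.0, -5.0]), np.array([5.0, 5.0]), integer_indices={0}
        )
        ess_solve(problem, ESSOptions(max_evaluations=2000, seed=2))
        assert seen
        for x in seen:
            assert x[0] == round(x[0])

    def test_history_monotone_and_reproducible(self, sphere_problem):
        r1 = ess_solve(sphere_problem(3), ESSOptions(max_evaluations=3000, seed=11))
        r2 = ess_solve(sphere_problem(3), ESSOptions(max_evaluations=3000, seed=11))
        values = [v for _c, v in r1.history]
        assert values == sorted(values, reverse=True)
        assert r1.history == r2.history
        np.testing.assert_array_equal(r1.best.x, r2.best.x)

    def test_budget_not_exceeded_beyond_one_batch(self, sphere_problem):
        budget = 500
        result = ess_solve(sphere_problem(4), ESSOptions(max_evaluations=budget, seed=5))
        # one batch = one Powell line search / go-beyond probe sequence
        assert result.total_evaluations <= budget + 8 * 4

    def test_budget_below_initialization_flagged(self, sphere_problem):
        result = ess_solve(
            sphere_problem(5), ESSOptions(max_evaluations=10, diverse_set_size=50, seed=0)
        )
        assert result.metadata.get("budget_exhausted_in_init")
        assert result.best is not None

    def test_refset_size_must_be_even_and_at_least_four(self, sphere_problem):
        with pytest.raises(ValueError):
            ess_solve(sphere_problem(2), ESSOptions(N=5, max_evaluations=100))
        with pytest.raises(ValueError):
            ess_solve(sphere_problem(2), ESSOptions(N=2, max_evaluations=100))
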