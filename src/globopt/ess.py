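"""Enhanced scatter search (eSS) for continuous and mixed-integer problems.

Scatter search keeps a small population (the *reference set*, RefSet) whose
members are combined systematically, pair by pair, rather than recombined at
random.  The enhancements implemented here:

* **1+1 replacement** — an offspring may replace only the RefSet member that
  generated it, never any other member.  This preserves diversity and
  prevents near-duplicates from accumulating in the RefSet.
* **go-beyond** — when an offspring outperforms its parent, the search
  extrapolates past the offspring along the parent-to-offspring direction,
  doubling the step while improvement continues.
* **memory-guided local search** — a bounded derivative-free refinement
  (Powell's method) started from the best RefSet member that is not too close
  to any previously refined point, so local searches are not wasted
  re-descending into known basins.
* **stagnation control** — members unchanged for many generations (except
  the incumbent best) are replaced by fresh diverse points.

Integer-constrained positions are rounded before every evaluation, frozen
during the continuous refinement, and polished afterwards by unit moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .problem import (
    EvaluationCounter,
    OptimizationProblem,
    Solution,
    SolverResult,
    evaluate,
    latin_hypercube,
)

__all__ = ["ESSOptions", "ESS", "ess_solve", "combine_pair", "go_beyond", "default_refset_size"]


def default_refset_size(nvar: int) -> int:
    """Small-population default: max(8, 1 + sqrt(2 n)) rounded up to even."""
    n = max(8, math.ceil(1 + math.sqrt(2 * nvar)))
    return n + (n % 2)


@dataclass
class ESSOptions:
    """Tunable settings of the eSS solver.

    ``N`` must be even and at least 4 (members are combined in pairs).
    ``local_search_interval`` counts iterations between refinements; the
    first refinement runs after the first iteration.
    ``local_search_filter_radius`` is measured in bound-width units.
    """

    N: int | None = None
    diverse_set_size: int | None = None
    max_evaluations: int = 10_000
    local_search_enabled: bool = True
    local_search_interval: int = 10
    local_search_max_evals: int | None = None
    local_search_filter_radius: float = 0.05
    stagnation_threshold: int = 20
    offspring_per_pair: int = 2
    combination_margin: float = 0.5
    seed: int | None = None

    def resolve(self, nvar: int) -> "ESSOptions":
        out = ESSOptions(**self.__dict__)
        if out.N is None:
            out.N = default_refset_size(nvar)
        if out.diverse_set_size is None:
            out.diverse_set_size = max(10 * nvar, out.N)
        if out.local_search_max_evals is None:
            out.local_search_max_evals = 500 * nvar
        if out.N < 4 or out.N % 2:
            raise ValueError("RefSet size N must be even and >= 4")
        for name in ("diverse_set_size", "max_evaluations", "local_search_interval",
                     "stagnation_threshold", "offspring_per_pair"):
            if getattr(out, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return out


def combine_pair(
    a: np.ndarray,
    a_penalized: float,
    b: np.ndarray,
    b_penalized: float,
    problem: OptimizationProblem,
    rng: np.random.Generator,
    n_offspring: int = 2,
    margin: float = 0.5,
) -> list[np.ndarray]:
    """Offspring vectors from the directed pair (a, b).

    Candidates are drawn uniformly from the hyper-rectangle spanned by the
    parents, stretched by ``margin`` times the per-coordinate parent distance
    on the better parent's side.  Identical parents yield small random
    perturbations of ``a`` instead (never an exact duplicate).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    width = problem.upper - problem.lower
    if np.array_equal(a, b):
        out = []
        for _ in range(n_offspring):
            for _attempt in range(20):
                c = problem.clip(a + rng.uniform(-0.01, 0.01, size=a.size) * np.where(width > 0, width, 1.0))
                if not np.array_equal(c, a):
                    break
            else:
                # fully degenerate box around a: move one free coordinate by a unit
                c = a.copy()
                for i in range(a.size):
                    if problem.upper[i] > problem.lower[i]:
                        step = 1.0 if i in problem.integer_indices else 0.01 * width[i]
                        c[i] = a[i] + step if a[i] + step <= problem.upper[i] else a[i] - step
                        break
                c = problem.clip(c)
            out.append(c)
        return out
    d = np.abs(b - a)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    better = a if a_penalized <= b_penalized else b
    extend_low = better <= lo + 1e-300  # better parent sits on the low face
    lo = np.where(extend_low, lo - margin * d, lo)
    hi = np.where(~extend_low, hi + margin * d, hi)
    return [problem.clip(rng.uniform(lo, hi)) for _ in range(n_offspring)]


def go_beyond(
    parent: Solution,
    offspring: Solution,
    problem: OptimizationProblem,
    counter: EvaluationCounter,
) -> Solution:
    """Extrapolate past an improving offspring along parent -> offspring.

    The probe step starts at the parent-to-offspring displacement and doubles
    after each improvement; the walk stops at the first non-improvement or
    when bound clipping leaves the probe in place.  Called with an offspring
    that does not beat its parent, it returns the offspring untouched.
    """
    if not offspring.penalized < parent.penalized:
        return offspring
    best = offspring
    step = offspring.x - parent.x
    while not counter.exhausted:
        cand = problem.clip(best.x + step)
        if np.array_equal(cand, best.x):
            break
        sol = evaluate(problem, cand, counter)
        if sol.penalized < best.penalized:
            best = sol
            step = step * 2.0
        else:
            break
    return best


class ESS:
    """Resumable eSS run; :func:`ess_solve` is the one-shot entry point.

    The solver advances in iterations of systematic pairwise combination.
    :meth:`run_until` stops at iteration boundaries once the evaluation count
    reaches a target, which lets cooperative threads advance in synchronized
    rounds without changing single-thread behavior.
    """

    batch_label = "one combination iteration"

    def __init__(self, problem: OptimizationProblem, options: ESSOptions | None = None):
        self.problem = problem
        self.options = (options or ESSOptions()).resolve(problem.nvar)
        self.rng = np.random.default_rng(self.options.seed)
        self.counter = EvaluationCounter(budget=self.options.max_evaluations)
        self.refset: list[Solution] = []
        self.stagnation: np.ndarray | None = None
        self.ls_archive: list[tuple[np.ndarray, np.ndarray]] = []
        self.iteration = 0
        self.metadata: dict = {}
        self._initialized = False

    # -- initialization ----------------------------------------------------

    def initialize(self) -> None:
        if self._initialized:
            return
        opts = self.options
        pts = latin_hypercube(self.problem.lower, self.problem.upper, opts.diverse_set_size, self.rng)
        evaluated = []
        for row in pts:
            if self.counter.exhausted:
                self.metadata["budget_exhausted_in_init"] = True
                break
            evaluated.append(evaluate(self.problem, self.problem.clip(row), self.counter))
        evaluated.sort(key=lambda s: s.penalized)
        n_quality = min(opts.N // 2, len(evaluated))
        refset = evaluated[:n_quality]
        pool = evaluated[n_quality:]
        width = np.where(self.problem.upper > self.problem.lower, self.problem.upper - self.problem.lower, 1.0)
        while len(refset) < opts.N and pool:
            # greedy max-min normalized distance to the current RefSet
            dists = [min(np.linalg.norm((s.x - r.x) / width) for r in refset) for s in pool]
            k = int(np.argmax(dists))
            refset.append(pool.pop(k))
        while len(refset) < opts.N and not self.counter.exhausted:
            x = self.problem.clip(latin_hypercube(self.problem.lower, self.problem.upper, 1, self.rng)[0])
            refset.append(evaluate(self.problem, x, self.counter))
        self.refset = refset
        self.stagnation = np.zeros(len(refset), dtype=int)
        self._initialized = True

    # -- main loop ---------------------------------------------------------

    def run_until(self, eval_target: float = math.inf) -> None:
        """Advance until the counter reaches ``eval_target`` or the budget."""
        self.initialize()
        while not self.counter.exhausted and self.counter.count < eval_target and self.refset:
            self.iteration += 1
            self._combination_iteration()
            if (
                self.options.local_search_enabled
                and self.iteration % self.options.local_search_interval == 1 % self.options.local_search_interval
                and not self.counter.exhausted
            ):
                self._memory_guided_local_search()
            self._handle_stagnation()

    def solve(self) -> SolverResult:
        self.run_until(math.inf)
        return self.result()

    def result(self) -> SolverResult:
        best = self.counter.best
        meta = dict(self.metadata, solver="ess", options={
            k: v for k, v in self.options.__dict__.items()})
        return SolverResult(
            best=best,
            history=list(self.counter.history),
            total_evaluations=self.counter.count,
            seed=self.options.seed,
            metadata=meta,
        )

    @property
    def best(self) -> Solution:
        return self.counter.best

    def inject(self, solution: Solution) -> None:
        """Adopt an externally supplied solution by replacing the worst
        RefSet member when the newcomer is strictly better (the member
        holding the current best is never displaced)."""
        self.initialize()
        if not self.refset:
            return
        worst = int(np.argmax([s.penalized for s in self.refset]))
        if solution.penalized < self.refset[worst].penalized:
            self.refset[worst] = solution
            self.stagnation[worst] = 0

    def _combination_iteration(self) -> None:
        opts = self.options
        n = len(self.refset)
        order = list(range(n))
        for i in order:
            if self.counter.exhausted:
                return
            parent = self.refset[i]
            best_child: Solution | None = None
            for j in range(n):
                if j == i:
                    continue
                mate = self.refset[j]
                for cand in combine_pair(
                    parent.x, parent.penalized, mate.x, mate.penalized,
                    self.problem, self.rng, opts.offspring_per_pair, opts.combination_margin,
                ):
                    if self.counter.exhausted:
                        break
                    sol = evaluate(self.problem, cand, self.counter)
                    if best_child is None or sol.penalized < best_child.penalized:
                        best_child = sol
                if self.counter.exhausted:
                    break
            if best_child is not None and best_child.penalized < parent.penalized:
                improved = go_beyond(parent, best_child, self.problem, self.counter)
                self.replace_member(i, improved)
            else:
                self.stagnation[i] += 1

    def replace_member(self, i: int, offspring: Solution) -> bool:
        """1+1 replacement: slot ``i`` changes iff its own offspring improved it."""
        if offspring.penalized < self.refset[i].penalized:
            self.refset[i] = offspring
            self.stagnation[i] = 0
            return True
        return False

    def _handle_stagnation(self) -> None:
        best_idx = int(np.argmin([s.penalized for s in self.refset]))
        for i in range(len(self.refset)):
            if i == best_idx or self.stagnation[i] < self.options.stagnation_threshold:
                continue
            if self.counter.exhausted:
                return
            x = self.problem.clip(latin_hypercube(self.problem.lower, self.problem.upper, 1, self.rng)[0])
            self.refset[i] = evaluate(self.problem, x, self.counter)
            self.stagnation[i] = 0

    # -- memory-guided local search ---------------------------------------

    def _normalized_dist(self, x: np.ndarray, y: np.ndarray) -> float:
        width = np.where(self.problem.upper > self.problem.lower, self.problem.upper - self.problem.lower, 1.0)
        return float(np.linalg.norm((x - y) / width) / math.sqrt(self.problem.nvar))

    def _memory_guided_local_search(self) -> None:
        radius = self.options.local_search_filter_radius
        order = np.argsort([s.penalized for s in self.refset])
        start_idx = None
        for i in order:
            s = self.refset[i]
            if all(self._normalized_dist(s.x, xf) > radius for _x0, xf in self.ls_archive):
                start_idx = int(i)
                break
        if start_idx is None:
            return
        start = self.refset[start_idx]
        refined = self._local_refine(start)
        self.ls_archive.append((start.x.copy(), refined.x.copy()))
        self.replace_member(start_idx, refined)

    def _local_refine(self, start: Solution) -> Solution:
        """Bounded Powell refinement over the continuous coordinates, integer
        coordinates frozen, followed by a unit-move polish of the integers."""
        problem = self.problem
        max_fev = min(self.options.local_search_max_evals, self.counter.remaining)
        if max_fev <= 1:
            return start
        cont = [i for i in range(problem.nvar) if i not in problem.integer_indices]
        best_holder = [start]
        if cont:
            template = start.x.copy()

            def fun(z: np.ndarray) -> float:
                x = template.copy()
                x[cont] = z
                sol = evaluate(problem, problem.clip(x), self.counter)
                if sol.penalized < best_holder[0].penalized:
                    best_holder[0] = sol
                return sol.penalized if math.isfinite(sol.penalized) else 1e300

            bounds = [(problem.lower[i], problem.upper[i]) for i in cont]
            try:
                minimize(
                    fun,
                    start.x[cont],
                    method="Powell",
                    bounds=bounds,
                    options={"maxfev": max_fev, "xtol": 1e-10, "ftol": 1e-12},
                )
            except Exception:
                pass  # a failed refinement leaves the best-seen point intact
        best = best_holder[0]
        # integer polish: first-improvement unit moves until a sweep fails
        ints = sorted(problem.integer_indices)
        improved = bool(ints)
        while improved and not self.counter.exhausted:
            improved = False
            for i in ints:
                for step in (1.0, -1.0):
                    cand = best.x.copy()
                    cand[i] += step
                    if cand[i] < problem.lower[i] or cand[i] > problem.upper[i]:
                        continue
                    if self.counter.exhausted:
                        return best
                    sol = evaluate(problem, cand, self.counter)
                    if sol.penalized < best.penalized:
                        best = sol
                        improved = True
                        break
        return best


def ess_solve(problem: OptimizationProblem, options: ESSOptions | None = None) -> SolverResult:
    """Run enhanced scatter search on ``problem`` and return the result."""
    return ESS(problem, options).solve()
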