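"""Variable neighborhood search (VNS) for integer programming.

A trajectory method: an incumbent integer vector is perturbed ("shaken") in
a neighborhood of distance ``k`` — exactly ``k`` decision variables redrawn
uniformly within their bounds — and an integer local search descends from
the shaken point.  Improvement recenters the trajectory and resets ``k`` to
1; failure widens the neighborhood (``k`` grows, wrapping at ``k_max``).
Two cycle-avoidance devices from large-scale practice are included:

* the set of perturbed variable indices may not repeat any set used in the
  recent shakes (bounded memory, deque of 10 by default);
* ``k`` is capped at ``k_max`` (decomposition-style cap, default
  ``min(nvar, 10)``) so shakes never degenerate into full restarts on large
  problems.

The local search uses first-improvement unit moves (±1 per coordinate in a
randomized order).  Each improving move is extended in the same direction
while improvement continues — the "go-beyond" idea carried over from the
continuous scatter-search world.  The *aggressive* profile performs a single
sweep, accepting the first improving move per coordinate, trading solution
quality for speed.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .problem import (
    EvaluationCounter,
    OptimizationProblem,
    Solution,
    SolverResult,
    evaluate,
)

__all__ = ["VNSOptions", "VNS", "vns_solve", "shake", "integer_local_search"]


@dataclass
class VNSOptions:
    max_evaluations: int = 10_000
    k_max: int | None = None          # cap on perturbed variables
    memory_size: int = 10             # recent perturbation sets remembered
    aggressive: bool = False
    seed: int | None = None

    def resolve(self, nvar: int) -> "VNSOptions":
        out = VNSOptions(**self.__dict__)
        if out.k_max is None:
            out.k_max = min(nvar, 10)
        out.k_max = max(1, min(out.k_max, nvar))
        if out.max_evaluations <= 0 or out.memory_size <= 0:
            raise ValueError("max_evaluations and memory_size must be positive")
        return out


def shake(
    x: np.ndarray,
    k: int,
    problem: OptimizationProblem,
    memory: deque,
    rng: np.random.Generator,
) -> tuple[np.ndarray, frozenset[int]]:
    """Perturb exactly ``k`` variables of ``x`` to new in-bounds values.

    The chosen index set must differ from every set in ``memory``; the set
    is then appended (oldest evicted by the deque bound).  A variable whose
    domain is a single value cannot change; a substitute index is drawn when
    possible.  If the memory has exhausted all index sets of size ``k``, it
    is cleared and the draw repeated.
    """
    nvar = x.size
    if not 1 <= k <= nvar:
        raise ValueError("k out of range")
    mutable = [i for i in range(nvar) if problem.upper[i] > problem.lower[i]]
    pool = mutable if len(mutable) >= k else list(range(nvar))
    total_sets = math.comb(len(pool), k)
    for attempt in range(1000):
        idx = frozenset(int(i) for i in rng.choice(len(pool), size=k, replace=False))
        idx = frozenset(pool[i] for i in idx)
        if idx not in memory:
            break
        if sum(1 for s in memory if len(s) == k) >= total_sets:
            memory.clear()
    memory.append(idx)
    x2 = x.astype(float).copy()
    for i in idx:
        lo, hi = int(problem.lower[i]), int(problem.upper[i])
        if hi == lo:
            continue  # degenerate domain: position left unchanged
        choices = [v for v in range(lo, hi + 1) if v != int(x[i])]
        x2[i] = float(choices[rng.integers(len(choices))])
    return x2, idx


def integer_local_search(
    x: np.ndarray,
    problem: OptimizationProblem,
    counter: EvaluationCounter,
    rng: np.random.Generator,
    aggressive: bool = False,
    start: Solution | None = None,
) -> Solution:
    """First-improvement unit-move descent with directional extension.

    Non-aggressive: repeat full sweeps over the coordinates (randomized
    order, ±1 moves) until a sweep yields no improvement; each improving
    move keeps stepping in its direction while it keeps improving.
    Aggressive: one single sweep.  Never returns a solution worse than the
    input.
    """
    best = start if start is not None else evaluate(problem, x, counter)
    while not counter.exhausted:
        improved_in_sweep = False
        order = rng.permutation(problem.nvar)
        for i in order:
            for direction in (1.0, -1.0):
                cand = best.x.copy()
                cand[i] += direction
                if cand[i] < problem.lower[i] or cand[i] > problem.upper[i]:
                    continue
                if counter.exhausted:
                    return best
                sol = evaluate(problem, cand, counter)
                if sol.penalized < best.penalized:
                    best = sol
                    improved_in_sweep = True
                    # go-beyond: extend the improving direction
                    while not counter.exhausted:
                        cand = best.x.copy()
                        cand[i] += direction
                        if cand[i] < problem.lower[i] or cand[i] > problem.upper[i]:
                            break
                        sol = evaluate(problem, cand, counter)
                        if sol.penalized < best.penalized:
                            best = sol
                        else:
                            break
                    break  # first improvement: move on to the next coordinate
        if aggressive or not improved_in_sweep:
            break
    return best


class VNS:
    """Resumable VNS run over an all-integer problem."""

    batch_label = "one shake + local search"

    def __init__(self, problem: OptimizationProblem, options: VNSOptions | None = None):
        if not problem.is_integer:
            raise ValueError("VNS requires an all-integer problem")
        if not np.all(np.isfinite(problem.lower)) or not np.all(np.isfinite(problem.upper)):
            raise ValueError("VNS requires finite bounds")
        self.problem = problem
        self.options = (options or VNSOptions()).resolve(problem.nvar)
        self.rng = np.random.default_rng(self.options.seed)
        self.counter = EvaluationCounter(budget=self.options.max_evaluations)
        self.memory: deque = deque(maxlen=self.options.memory_size)
        self.incumbent: Solution | None = None
        self.k = 1
        self.metadata: dict = {}
        self._initialized = False

    def initialize(self) -> None:
        if self._initialized:
            return
        problem = self.problem
        x0 = problem.clip(np.array([
            self.rng.integers(int(problem.lower[i]), int(problem.upper[i]) + 1)
            for i in range(problem.nvar)
        ], dtype=float))
        start = evaluate(problem, x0, self.counter)
        self.incumbent = integer_local_search(
            x0, problem, self.counter, self.rng, self.options.aggressive, start=start
        )
        self._initialized = True

    def run_until(self, eval_target: float = math.inf) -> None:
        self.initialize()
        sizes = self.problem.upper - self.problem.lower + 1
        if float(np.prod(sizes)) <= 1:
            return  # single-point search space: nothing beyond the first evaluation
        while not self.counter.exhausted and self.counter.count < eval_target:
            shaken, _idx = shake(self.incumbent.x, self.k, self.problem, self.memory, self.rng)
            candidate = integer_local_search(
                shaken, self.problem, self.counter, self.rng, self.options.aggressive
            )
            if candidate.penalized < self.incumbent.penalized:
                self.incumbent = candidate
                self.k = 1
            else:
                self.k = self.k + 1 if self.k < self.options.k_max else 1

    def inject(self, solution: Solution) -> None:
        """Adopt an externally supplied incumbent if it is strictly better."""
        self.initialize()
        if solution.penalized < self.incumbent.penalized:
            self.incumbent = solution
            self.k = 1

    def solve(self) -> SolverResult:
        self.run_until(math.inf)
        return self.result()

    def result(self) -> SolverResult:
        meta = dict(self.metadata, solver="vns", options=dict(self.options.__dict__))
        return SolverResult(
            best=self.counter.best,
            history=list(self.counter.history),
            total_evaluations=self.counter.count,
            seed=self.options.seed,
            metadata=meta,
        )

    @property
    def best(self) -> Solution:
        return self.counter.best


def vns_solve(problem: OptimizationProblem, options: VNSOptions | None = None) -> SolverResult:
    """Run variable neighborhood search on an all-integer ``problem``."""
    return VNS(problem, options).solve()
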