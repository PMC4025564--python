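"""Problem and solution data model shared by all solvers.

An :class:`OptimizationProblem` wraps a black-box objective together with box
bounds, an optional set of integer-constrained variables, and optional
inequality constraints handled by a penalty merit function.  Problems fall
into three classes depending on ``integer_indices``: continuous nonlinear
programs (empty set), mixed-integer nonlinear programs (proper subset), and
pure integer programs (all variables).

The objective callable receives a decision vector and returns either a scalar
``f`` or a pair ``(f, residuals)`` where ``residuals`` is a vector of
constraint values checked against ``constraint_lower``/``constraint_upper``.
Every evaluation passes through :func:`evaluate`, which charges exactly one
unit to an :class:`EvaluationCounter` — local searches and inner problems are
accounted against the same global budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OptimizationProblem",
    "Solution",
    "SolverResult",
    "EvaluationCounter",
    "evaluate",
    "latin_hypercube",
]


@dataclass
class OptimizationProblem:
    """Black-box optimization problem with box bounds and optional constraints.

    Parameters
    ----------
    objective
        Callable ``x -> f`` or ``x -> (f, residuals)``.
    lower, upper
        Bound vectors of equal length ``nvar`` with ``lower[i] <= upper[i]``.
    integer_indices
        Positions constrained to integer values.  Bounds at these positions
        are rounded inward to integers (``ceil`` for lower, ``floor`` for
        upper) so every representable value is feasible.
    constraint_lower, constraint_upper
        Per-constraint bounds on the residual vector; ``None`` entries mean
        unbounded on that side.
    penalty_weight
        Nonnegative weight ``w`` of the merit function
        ``penalized = f + w * violation``.
    name
        Optional label carried into results.
    """

    objective: Callable
    lower: np.ndarray
    upper: np.ndarray
    integer_indices: frozenset[int] = frozenset()
    constraint_lower: np.ndarray | None = None
    constraint_upper: np.ndarray | None = None
    penalty_weight: float = 1e3
    name: str = "problem"

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float).copy()
        self.upper = np.asarray(self.upper, dtype=float).copy()
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if np.any(self.lower > self.upper):
            raise ValueError("lower[i] <= upper[i] violated")
        self.integer_indices = frozenset(int(i) for i in self.integer_indices)
        if self.integer_indices and not self.integer_indices <= set(range(self.nvar)):
            raise ValueError("integer_indices out of range")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be nonnegative")
        # round bounds inward so integer variables have integral feasible bounds
        for i in self.integer_indices:
            self.lower[i] = math.ceil(self.lower[i] - 1e-9)
            self.upper[i] = math.floor(self.upper[i] + 1e-9)
            if self.lower[i] > self.upper[i]:
                raise ValueError(f"integer variable {i} has empty domain")
        if self.constraint_lower is not None:
            self.constraint_lower = np.asarray(self.constraint_lower, dtype=float)
        if self.constraint_upper is not None:
            self.constraint_upper = np.asarray(self.constraint_upper, dtype=float)

    @property
    def nvar(self) -> int:
        return self.lower.size

    @property
    def is_integer(self) -> bool:
        """True when every variable is integer-constrained (an IP)."""
        return len(self.integer_indices) == self.nvar

    @property
    def is_mixed_integer(self) -> bool:
        return 0 < len(self.integer_indices) < self.nvar

    def round_integers(self, x: np.ndarray) -> np.ndarray:
        """Round integer positions to the nearest in-bounds integer."""
        x = np.array(x, dtype=float)
        for i in self.integer_indices:
            x[i] = min(max(round(x[i]), self.lower[i]), self.upper[i])
        return x

    def clip(self, x: np.ndarray) -> np.ndarray:
        return self.round_integers(np.clip(x, self.lower, self.upper))


@dataclass(frozen=True)
class Solution:
    """A decision vector with its raw and penalized objective values."""

    x: np.ndarray
    f: float
    violation: float = 0.0
    penalized: float = 0.0

    def __repr__(self) -> str:  # compact: vectors can be long
        return f"Solution(f={self.f:.6g}, violation={self.violation:.3g}, penalized={self.penalized:.6g})"


@dataclass
class SolverResult:
    """Outcome of a solver run.

    ``history`` records ``(evaluation_count, best_penalized_so_far)`` pairs
    whose second components are non-increasing; it supports convergence
    curves without storing every evaluation.
    """

    best: Solution
    history: list[tuple[int, float]]
    total_evaluations: int
    seed: int | None
    metadata: dict = field(default_factory=dict)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history, columns=["evaluations", "best_value"])


class EvaluationCounter:
    """Counts objective evaluations and records the best-so-far history.

    A ``budget`` makes :attr:`exhausted` flip once ``count >= budget``;
    solvers poll it between atomic operations, so the budget may be exceeded
    only by the size of the current inner batch.
    """

    def __init__(self, budget: int | None = None):
        self.count = 0
        self.budget = budget
        self.best: Solution | None = None
        self.history: list[tuple[int, float]] = []

    @property
    def exhausted(self) -> bool:
        return self.budget is not None and self.count >= self.budget

    @property
    def remaining(self) -> int:
        if self.budget is None:
            return 2**62
        return max(0, self.budget - self.count)

    def record(self, sol: Solution) -> None:
        self.count += 1
        if self.best is None or sol.penalized < self.best.penalized:
            self.best = sol
            self.history.append((self.count, sol.penalized))


def evaluate(problem: OptimizationProblem, x: Sequence[float], counter: EvaluationCounter) -> Solution:
    """Evaluate ``problem.objective`` at ``x``, charging one evaluation.

    Constraint residuals outside ``[constraint_lower, constraint_upper]``
    contribute their excess magnitude to ``violation``.  A non-finite
    objective value yields ``penalized = +inf`` rather than an error, so the
    search can continue around undefined regions.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (problem.nvar,):
        raise ValueError(f"decision vector has shape {x.shape}, expected ({problem.nvar},)")
    out = problem.objective(x)
    if isinstance(out, tuple):
        f, residuals = out
        residuals = np.atleast_1d(np.asarray(residuals, dtype=float))
    else:
        f, residuals = out, None
    f = float(f)
    violation = 0.0
    if residuals is not None:
        if problem.constraint_upper is not None:
            cu = problem.constraint_upper
            violation += float(np.sum(np.maximum(residuals - cu, 0.0)[np.isfinite(cu)]))
        if problem.constraint_lower is not None:
            cl = problem.constraint_lower
            violation += float(np.sum(np.maximum(cl - residuals, 0.0)[np.isfinite(cl)]))
    if not math.isfinite(f) or not math.isfinite(violation):
        sol = Solution(x=x.copy(), f=f, violation=violation, penalized=math.inf)
    else:
        sol = Solution(
            x=x.copy(),
            f=f,
            violation=violation,
            penalized=f + problem.penalty_weight * violation,
        )
    counter.record(sol)
    return sol


def latin_hypercube(
    lower: Sequence[float],
    upper: Sequence[float],
    n_points: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Latin hypercube sample: one point per equal-width stratum per axis.

    Degenerate coordinates (``lower == upper``) collapse to the constant
    value.  Identical seeds give identical matrices.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    nvar = lower.size
    u = (rng.permuted(np.tile(np.arange(n_points), (nvar, 1)), axis=1).T + rng.uniform(size=(n_points, nvar))) / n_points
    return lower + u * (upper - lower)
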