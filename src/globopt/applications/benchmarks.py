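"""Benchmark objective functions: continuous test suite + gear train.

The continuous registry provides the classic multimodal/unimodal test
functions (sphere, Rosenbrock, Rastrigin, Ackley, Schwefel) plus shifted and
rotated variants in the spirit of large-scale global-optimization
competition suites: the optimum is moved off the origin by a shift vector
and the coordinate system mixed by a random orthogonal matrix.  Shifts and
rotations are regenerated deterministically from a fixed seed derived from
the function name and dimension, so every call sees the same landscape.

The gear-train problem is a classic integer design benchmark: choose four
gear teeth counts in [12, 60] so the compound transmission ratio
x1*x2/(x3*x4) approximates 1/6.931; the objective is the squared deviation.
Its global minimum over the full 49^4 grid is ~2.7009e-12 at (16,19,43,49).
"""

from __future__ import annotations

import numpy as np

from ..problem import OptimizationProblem

__all__ = [
    "sphere",
    "rosenbrock",
    "rastrigin",
    "ackley",
    "schwefel",
    "benchmark_function",
    "benchmark_registry",
    "make_benchmark_problem",
    "gear_train",
    "gear_train_problem",
    "enumerate_gear_train",
    "GEAR_RATIO_TARGET",
]


def sphere(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(np.sum(x * x))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def ackley(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    n = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


def schwefel(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(418.9829 * x.size - np.sum(x * np.sin(np.sqrt(np.abs(x)))))


_BASE = {
    # name: (function, canonical box per coordinate, optimum location value)
    "sphere": (sphere, (-100.0, 100.0), 0.0),
    "rosenbrock": (rosenbrock, (-30.0, 30.0), 1.0),
    "rastrigin": (rastrigin, (-5.12, 5.12), 0.0),
    "ackley": (ackley, (-32.0, 32.0), 0.0),
    "schwefel": (schwefel, (-500.0, 500.0), 420.968746),
}


def _variant_seed(name: str, nvar: int) -> int:
    # stable, documented derivation: landscapes are identical across runs
    return (abs(hash_str(name)) + 7919 * nvar) % (2**31)


def hash_str(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


def _shift_and_rotation(base: str, nvar: int, rotated: bool) -> tuple[np.ndarray, np.ndarray | None]:
    fn, (lo, hi), x_opt = _BASE[base]
    rng = np.random.default_rng(_variant_seed(base, nvar))
    # keep the shifted optimum comfortably inside the box
    shift = x_opt + rng.uniform(0.2 * lo, 0.2 * hi, size=nvar)
    rot = None
    if rotated:
        q, r = np.linalg.qr(rng.normal(size=(nvar, nvar)))
        rot = q * np.sign(np.diag(r))  # unique orthogonal factor
    return shift, rot


def benchmark_registry(nvar: int) -> dict[str, dict]:
    """Registry of benchmark entries for dimension ``nvar``.

    Each entry holds ``fun`` (vector -> scalar), ``lower``/``upper`` bound
    vectors, the known global minimum value ``f_min`` and a minimizer
    ``x_min`` — the latter two let tests assert convergence targets.
    """
    reg: dict[str, dict] = {}
    for name, (fn, (lo, hi), x_opt) in _BASE.items():
        x_min = np.full(nvar, x_opt)
        reg[name] = {
            "fun": fn,
            "lower": np.full(nvar, lo),
            "upper": np.full(nvar, hi),
            "f_min": fn(x_min),
            "x_min": x_min,
        }
    for base in ("sphere", "rastrigin", "ackley"):
        fn, (lo, hi), x_opt = _BASE[base]
        for rotated in (False, True):
            name = f"{'rotated_' if rotated else ''}shifted_{base}"
            shift, rot = _shift_and_rotation(base, nvar, rotated)

            def make(fn=fn, shift=shift, rot=rot):
                def wrapped(x: np.ndarray) -> float:
                    z = np.asarray(x, float) - shift
                    if rot is not None:
                        z = rot @ z
                    return fn(z)
                return wrapped

            reg[name] = {
                "fun": make(),
                "lower": np.full(nvar, lo),
                "upper": np.full(nvar, hi),
                "f_min": 0.0,
                "x_min": shift.copy(),
            }
    return reg


def benchmark_function(name: str, x: np.ndarray) -> float:
    """Evaluate registry function ``name`` at ``x`` (dimension from ``x``)."""
    x = np.asarray(x, float)
    reg = benchmark_registry(x.size)
    if name not in reg:
        raise KeyError(f"unknown benchmark {name!r}; available: {sorted(reg)}")
    entry = reg[name]
    if np.any(x < entry["lower"]) or np.any(x > entry["upper"]):
        raise ValueError(f"{name}: x outside the canonical box")
    return entry["fun"](x)


def make_benchmark_problem(name: str, nvar: int, penalty_weight: float = 1e3) -> OptimizationProblem:
    reg = benchmark_registry(nvar)
    if name not in reg:
        raise KeyError(f"unknown benchmark {name!r}; available: {sorted(reg)}")
    e = reg[name]
    return OptimizationProblem(
        objective=e["fun"], lower=e["lower"], upper=e["upper"],
        penalty_weight=penalty_weight, name=name,
    )


# -- gear train ----------------------------------------------------------

GEAR_RATIO_TARGET = 1.0 / 6.931


def gear_train(x) -> float:
    """Squared deviation of the compound gear ratio x1*x2/(x3*x4) from 1/6.931."""
    x = np.asarray(x, float)
    if x.shape != (4,):
        raise ValueError("gear train takes 4 teeth counts")
    if np.any(np.abs(x - np.round(x)) > 1e-9):
        raise ValueError("teeth counts must be integers")
    if np.any(x < 12) or np.any(x > 60):
        raise ValueError("teeth counts must lie in [12, 60]")
    return float((GEAR_RATIO_TARGET - (x[0] * x[1]) / (x[2] * x[3])) ** 2)


def gear_train_problem() -> OptimizationProblem:
    return OptimizationProblem(
        objective=gear_train,
        lower=np.full(4, 12.0),
        upper=np.full(4, 60.0),
        integer_indices=frozenset(range(4)),
        name="gear_train",
    )


def enumerate_gear_train() -> tuple[float, tuple[int, int, int, int]]:
    """Exhaustive minimum over the full 49^4 grid (vectorized; independent
    oracle for the stochastic solvers)."""
    teeth = np.arange(12, 61)
    prod = np.multiply.outer(teeth, teeth).ravel().astype(float)  # 2401 products
    vals = (GEAR_RATIO_TARGET - np.divide.outer(prod, prod)) ** 2  # all 49^4 ratios
    flat = int(np.argmin(vals))
    i, j = np.unravel_index(flat, vals.shape)
    a1, a2 = np.unravel_index(i, (49, 49))
    b1, b2 = np.unravel_index(j, (49, 49))
    return float(vals[i, j]), (int(teeth[a1]), int(teeth[a2]), int(teeth[b1]), int(teeth[b2]))
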