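import numpy as np
import pytest

from globopt.problem import OptimizationProblem


def sphere(x):
    return float(np.sum(np.asarray(x, float) ** 2))


def rosenbrock(x):
    x = np.asarray(x, float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def rastrigin(x):
    x = np.asarray(x, float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


@pytest.fixture
def sphere_problem():
    def make(nvar=5, half_width=5.0):
        return OptimizationProblem(
            sphere, np.full(nvar, -half_width), np.full(nvar, half_width), name="sphere"
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
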