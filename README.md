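# globopt

Metaheuristic global optimization for systems biology and bioinformatics.

Many problems in computational biology reduce to minimizing a black-box
objective that is non-convex, noisy at the edges, and expensive: calibrating
a kinetic or logic model against data, choosing gene knockouts that maximize
production of a metabolite, or solving combinatorial design problems.
Gradient-based and exact methods struggle here — the landscapes are
multimodal and the decision variables are often integers.  `globopt`
provides the metaheuristics that practitioners reach for in this setting:

- **eSS** (`ess_solve`) — enhanced scatter search for continuous (cNLP) and
  mixed-integer (MINLP) problems.  A small reference set of solutions is
  combined systematically pair by pair; an offspring may replace only the
  member that generated it (1+1 replacement), promising directions are
  extrapolated past the offspring with doubling steps ("go-beyond"), and a
  memory-filtered Powell local search refines the best unexplored member.
- **VNS** (`vns_solve`) — variable neighborhood search for integer problems
  (IP).  Shakes perturb exactly *k* variables (never repeating a recent
  index set), a first-improvement unit-move descent with directional
  extension follows, and *k* grows on failure and resets on success.
- **CeSS / CVNS** (`cooperative_solve`) — η threads with profiles spanning
  conservative (diversification) to aggressive (intensification) advance in
  synchronous rounds of τ evaluations and broadcast the best solution found.
- **Bayesian sampling** (`bayesfit_sample`) — multi-start adaptive
  Metropolis–Hastings over a bounded parameter box.  Instead of a single
  best fit you get the posterior: marginal histograms, quantiles, and
  pairwise covariation maps that expose parameter non-identifiability.

The `globopt.applications` package supplies the case-study objectives:
training Boolean logic models of signaling networks to perturbation data
(`theta = theta_f + alpha * theta_s`, mean-squared readout error plus a
size penalty proportional to gate input counts), gene-knockout strain
design with a flux-balance-analysis LP inside the objective, the gear-train
integer design benchmark, and classic continuous test functions with
shifted/rotated variants.  Seeded fixture generators (`globopt.fixtures`)
create every test input programmatically and record the exhaustively
computed ground truth alongside.

## Worked example

Calibrate a 5-parameter curved-valley objective (Rosenbrock) with eSS:

```python
import numpy as np
from globopt import OptimizationProblem, ESSOptions, ess_solve

def rosenbrock(x):
    x = np.asarray(x)
    return float(np.sum(100 * (x[1:] - x[:-1]**2)**2 + (1 - x[:-1])**2))

problem = OptimizationProblem(rosenbrock, lower=np.full(5, -5.0), upper=np.full(5, 10.0))
result = ess_solve(problem, ESSOptions(max_evaluations=50_000, seed=1))
print("best f :", result.best.f)
print("best x :", np.round(result.best.x, 6))
print("evals  :", result.total_evaluations)
```

```
best f : 6.05660171949359e-20
best x : [1. 1. 1. 1. 1.]
evals  : 50000
```

The solver finds the global optimum at (1, …, 1) to floating-point
accuracy within the 50,000-evaluation budget; `result.history` holds the
monotone best-so-far curve for convergence plots.

The same run from the command line, with results written as JSON + CSV:

```bash
globopt solve --method ess --problem sphere --nvar 10 --budget 10000 --seed 1 --out out/
# best penalized objective: 1.44386475442e-45 after 10000 evaluations
```

Integer design with VNS (gear train: choose four teeth counts in [12, 60]
so that x1·x2/(x3·x4) ≈ 1/6.931):

```python
from globopt.applications.benchmarks import gear_train_problem
from globopt import VNSOptions, vns_solve

r = vns_solve(gear_train_problem(), VNSOptions(max_evaluations=20_000, seed=2))
print(r.best.penalized, r.best.x)   # 9.921579583985335e-10 [12. 13. 47. 23.]
```

A squared ratio deviation of 1e-9 means the transmission ratio is matched
to about 3×10⁻⁵; the grid's true optimum, 2.7009e-12 at (16, 19, 43, 49),
is confirmed by `enumerate_gear_train()` and reached by VNS at larger
budgets (see `docs/methods.md` for the basin analysis).

Fixtures and Bayesian runs follow the same pattern:

```bash
globopt fixtures --kind logic --seed 0 --out fixtures/logic/
globopt solve --method bayesfit --seed 1 --out out/bayes/
globopt summarize --chains out/bayes/ --out out/posterior.json
```

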