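# Methods

`globopt` implements a small family of metaheuristic global optimizers for
the problem classes that dominate model calibration and design in systems
biology — continuous nonlinear programs (cNLP), mixed-integer nonlinear
programs (MINLP) and pure integer programs (IP) — together with a Bayesian
sampler for parameter posteriors and a set of packaged application
objectives.  This note records the algorithms, the parameters that matter,
the numerical choices made where the design was genuinely open, and what
the synthetic test problems do and do not demonstrate.

## Problem model and evaluation accounting

All solvers treat the objective as a black box `x -> f` (optionally
`x -> (f, residuals)` for constrained problems).  Constraints are handled
by a single penalty merit function,

    penalized = f + w * violation,

where `violation` is the total magnitude by which residuals exceed their
bounds and `w` (default 1e3) is configurable.  This is the simplest
monotone merit function; no repair operators or adaptive penalties are
used.  Non-finite objective values are mapped to `+inf` rather than
raising, so the search can skirt undefined regions of parameter space (a
common occurrence when the objective integrates an ODE model).

Every call to the objective — including calls made inside local searches
and inner problems — charges exactly one unit against the global
evaluation budget.  Budgets are therefore comparable across solvers and
hardware.  Solvers poll the budget between atomic operations, so a run may
exceed its budget only by the size of one inner batch (one combination
sweep, one line search).

## Enhanced scatter search (eSS)

Scatter search maintains a small reference set (RefSet) of N solutions
(default `max(8, 1 + sqrt(2 n))` rounded up to even) initialized from a
Latin-hypercube diverse set (default `10 n` points): the best half by
quality, the rest by greedy max–min normalized distance.  Each iteration
combines every directed member pair: offspring are sampled uniformly in
the hyper-rectangle spanned by the two parents, stretched by half the
parent distance on the better parent's side (2 offspring per pair).
Three enhancements drive performance:

- **1+1 replacement.**  An offspring can replace only the member that
  generated it, and only on strict improvement.  Ties retain the
  incumbent, which keeps histories deterministic and the RefSet diverse.
- **Go-beyond.**  When an offspring beats its parent, probes are placed
  past the offspring along the parent→offspring direction, the step
  doubling after every improvement, stopping at the first failure or when
  bound clipping pins the probe.
- **Memory-guided local search.**  Every `local_search_interval`
  iterations (default 10; first refinement after iteration 1) the best
  member farther than `local_search_filter_radius` (default 0.05 in
  bound-width units) from all previously refined endpoints is refined with
  a bounded Powell direct search (`xtol 1e-10`, `ftol 1e-12`, budget
  `500 n` evaluations).  Powell was chosen over a simplex method because
  its directional line searches track curved valleys (Rosenbrock-type
  landscapes) far more reliably in 10+ dimensions while remaining
  derivative-free.  The archive of refined endpoints persists across
  member regenerations and prevents repeated descents into known basins.

Integer variables are rounded to the nearest in-bounds integer before
every evaluation (fractional integer points are never evaluated), frozen
during Powell refinement, and polished afterwards by first-improvement
unit moves.  Members unchanged for `stagnation_threshold` generations
(default 20, global best exempt) are replaced by fresh diverse points.

## Variable neighborhood search (VNS)

VNS is a trajectory method for all-integer problems with finite bounds.
A shake perturbs exactly `k` decision variables of the incumbent, each to
a uniformly drawn in-bounds value different from its current one; the
neighborhood distance is the cardinality of the perturbed set.  Cycle
avoidance follows large-scale practice: the perturbed index set may not
repeat any of the last 10 shakes, and `k` is capped at
`k_max = min(n, 10)` (a decomposition-style cap).  The local search is a
first-improvement descent: coordinates visited in randomized order, ±1
moves, each improving move extended in its direction while improvement
continues (the go-beyond idea transplanted to the integer lattice; for
objectives unimodal along a coordinate this reaches the conditional
optimum of that coordinate).  Improvement recenters the trajectory and
resets `k` to 1; failure increments `k`, wrapping at `k_max`.  Ties are
never accepted, which prevents cycling on plateaus.  The *aggressive*
profile stops after a single sweep — lower-quality local optima reached in
a fraction of the evaluations — and exists mainly as an intensification
endpoint for cooperative runs.

## Cooperation (CeSS / CVNS)

η solver threads advance in synchronous rounds of τ evaluations each
(defaults η = 4, τ = 2500).  Thread profiles interpolate from conservative
(eSS: larger RefSet, rarer local search; VNS: wider `k_max`,
non-aggressive) to aggressive (small RefSet, frequent local search;
single-sweep VNS).  After each round the global best is broadcast: an eSS
thread replaces its worst RefSet member (never its own best, protecting
diversity), a VNS thread adopts the solution as incumbent; optionally the
leading thread's second-best member is shared too.  Two deliberate
choices favor reproducibility over literal parallelism: rounds are
measured in evaluations rather than wall-clock time, and the threads run
round-robin in one process — the synchronous-barrier semantics make the
result independent of scheduling, so a fixed seed vector yields a
bit-identical result.  With η = 1 no exchange occurs (a thread's own best
is never re-injected into it) and the run is exactly the plain solver.

## Multi-start Metropolis–Hastings sampling

Parameter posteriors are sampled by several independent Gaussian
random-walk chains started from distinct uniform draws inside the bounding
box.  Per-parameter proposal scales start at 5% of the bound width and
adapt multiplicatively (×1.1 / ÷1.1 per 50-step window outside the
0.2–0.45 acceptance band) during the burn-in half of the chain only;
retained samples therefore come from a fixed-kernel chain.  Out-of-box
proposals are rejected (a uniform-prior indicator).  Note an interaction
worth knowing: on a posterior that is flat inside the box, every in-support
proposal is accepted, so adaptation grows the step until box rejections
pull the overall acceptance rate back into the target band — the
*in-support* acceptance probability is still 1.  Chains are pooled for
marginal histograms, quantiles (2.5/25/50/75/97.5%) and pairwise 2-D
histograms whose row/column sums match the 1-D histograms exactly;
multimodal or ridge-shaped histograms are the practical signature of
non-identifiability.  No between-chain convergence diagnostic is computed;
the multi-start design plus the conjugate-recovery and visit-frequency
tests stand in for it at the scale of the packaged problems.

## Application objectives

**Logic-model training.**  A signed directed network is expanded into
candidate hyperedges: every subset (up to fan-in 4) of the edges entering
a node becomes an AND gate; OR arises implicitly when several selected
gates share an output.  Predictions are logical steady states: synchronous
Boolean updates from an all-zero (non-stimulus) start, stimuli clamped,
inhibited nodes forced to 0, iterated to a fixed point or at most
`2 * n_nodes` sweeps; nodes still changing at the cutoff are *undefined*
and contribute the worst-case residual 1 per data point, which penalizes
oscillatory models consistently with steady-state semantics.  The training
score is `theta = theta_f + alpha * theta_s`, with `theta_f` the mean
squared residual over defined data points and `theta_s` the selected input
count normalized by the total input count over all candidates (a 3-input
AND gate costs three times a single edge).  The binary encoding is primary;
search-space compression to non-redundant gate combinations is not
implemented.

**Knockout design by FBA.**  The inner problem is flux balance analysis:
maximize biomass subject to `S v = 0` and flux bounds (solved with the
HiGHS LP solver via `scipy.optimize.linprog`).  Because the biomass
optimum is typically degenerate in the remaining fluxes, a secondary LP
maximizes the target-metabolite flux at fixed optimal biomass, making the
black box single-valued and deterministic.  The design encoding uses 5
integer slots over 0..52 (0 = unused); duplicate gene picks are collapsed
inside the objective, so the encoding is insensitive to slot order.
Infeasible or zero-growth designs score 0.  The packaged model is a
*synthetic* central-carbon sketch (fixed uptake, glycolysis with
redox/energy co-products, biomass, two fermentation isozymes, a target
route that costs energy): redox balance forces fermentation and energy
stringency keeps the target route closed until both isozymes are knocked
out, so the unique best design ({ethanol_a, ethanol_b}, target flux 20/3)
is verifiable by brute-force enumeration of all ≤3-gene sets (cached at
reaction-pattern level, a few dozen LP solves).

**Benchmarks.**  Classic continuous test functions (sphere, Rosenbrock,
Rastrigin, Ackley, Schwefel) plus shifted and rotated variants; shift
vectors and orthogonal rotation matrices are regenerated at run time from
a fixed seed derived from the function name and dimension, so the
landscapes are identical across runs without shipping matrix files.  The
gear-train problem — four integer teeth counts in [12, 60], objective the
squared deviation of `x1*x2/(x3*x4)` from 1/6.931 — has its global
optimum 2.7009e-12 at (16, 19, 43, 49), confirmed by a vectorized
exhaustive enumeration of all 49⁴ designs that runs in seconds.

## Synthetic fixtures: what they show and what they do not

All test inputs are generated programmatically with recorded ground truth
(a sidecar JSON written next to the data files).  The logic fixture is an
8-node network with 10 candidate gates; data are steady states of a known
6-gate sub-model under all 8 stimulus/inhibitor combinations with additive
Gaussian noise (sd 0.05) truncated into [0, 1); at the recorded
`alpha = 0.01` the generating selection is the exhaustive-enumeration
minimizer of theta, so solver recovery is checked against an absolute
answer.  The posterior fixture is a Hill transfer-function fit
(`y = x^n / (x^n + k^n)`, true n = 3, k = 0.5, Gaussian noise sd 0.05) —
the building block of logic-ODE models, small enough for closed-form
sanity checks.  These fixtures exercise the machinery end to end but are
deliberately easy: real signaling networks bring larger selection spaces,
correlated measurement error, and model misspecification, none of which
the fixtures emulate.  Passing recovery tests therefore validates the
solvers and objective implementations, not the biology of any particular
network.

## Problem sizes and numerical choices

Test and verification runs use desk-scale sizes chosen to keep oracles
exhaustive: 10-D continuous benchmarks with budgets of 10⁴–2×10⁵
evaluations; integer panels with ≤ 5 variables and ≤ 8 values so
enumeration is exact; 2×10⁵ MCMC steps for visit-frequency checks; the
oracle-equivalence panel for VNS uses random positive-definite integer
quadratics with off-grid centers — a structured family in which
neighborhood search is meaningful (on i.i.d. random lookup tables no
search can beat uniform sampling, so they are used only at sizes the
budget covers exhaustively).

One benchmark result deserves an honest caveat.  The gear-train global
optimum (2.70e-12) has a very small basin of attraction under unit-move
descent: sampled from uniform starts, roughly 1 descent in 10⁴ ends there,
at ~70 evaluations per descent.  A 20,000-evaluation VNS run performs
~270 descents, so the expected number of hits per run is a few percent;
at that budget ten seeded runs typically return ~1e-9 (the best
non-global 1-opt points) rather than the optimum.  The optimum is reached
at larger budgets — e.g. a 3×10⁵-evaluation run finds (19, 16, 43, 49)
exactly — and the enumeration oracle confirms 2.7009e-12 is the floor.
The acceptance script reports whatever the 10 × 20,000 protocol actually
achieves.

Other numerical choices: Latin-hypercube sampling uses one point per
equal-width stratum per axis with in-stratum jitter; degenerate bounds
(lower = upper) collapse that coordinate without error.  Distances used
for RefSet diversity and local-search filtering are Euclidean after
normalizing by bound widths.  All randomness flows from
`numpy.random.default_rng` seeded per run; equal seeds give bit-identical
histories, and solver histories are monotone best-so-far sequences of
(evaluation count, value) pairs.

## Known limitations

- Penalty constraint handling only; no feasibility repair, no equality
  constraint support beyond two-sided residual bounds.
- VNS requires finite integer bounds and enumerable domains per
  coordinate; it is not suited to cNLPs.
- The sampler's adaptation targets a fixed acceptance band and does not
  estimate the posterior covariance; strongly correlated posteriors mix
  slowly (visible as inflated autocorrelation, as in the 2-state test).
- Cooperation is single-process by design; it models the information
  topology of a parallel run, not its wall-clock speedup.
- The FBA application handles reaction knockouts through a many-to-one
  gene map; no gene-protein-reaction Boolean logic is implemented.
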