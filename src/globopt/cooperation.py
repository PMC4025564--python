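"""Cooperative multi-thread strategy for eSS and VNS (CeSS / CVNS).

η solver threads with heterogeneous settings — spanning *conservative*
(diversification-heavy: large population, rare local search, wide
neighborhoods) to *aggressive* (intensification-heavy: small population,
frequent local search, single-sweep descent) — advance in synchronous
rounds of τ objective evaluations each.  After every round the best solution
found anywhere is broadcast to all threads: an eSS thread folds it in by
replacing its worst RefSet member (never its own best), a VNS thread adopts
it as incumbent; optionally the leading eSS thread's second-best member is
shared as well.  Rounds are measured in evaluations, not wall-clock time,
so runs are deterministic and hardware-independent; the threads execute
round-robin in a single process, which satisfies the synchronous-barrier
contract without concurrency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ess import ESS, ESSOptions
from .problem import OptimizationProblem, Solution, SolverResult
from .vns import VNS, VNSOptions

__all__ = ["CooperationConfig", "cooperative_solve", "make_profiles"]


@dataclass
class CooperationConfig:
    """Settings of a cooperative run.

    ``tau`` is the per-thread, per-round evaluation quota; ``total_rounds``
    times ``tau`` is each thread's budget.  ``thread_profiles`` (one option
    set per thread) defaults to :func:`make_profiles` over the base options.
    """

    eta: int = 4
    tau: int = 2_500
    total_rounds: int = 10
    share_refset: bool = False
    thread_profiles: list | None = None
    seeds: list[int] | None = None
    base_options: object | None = None

    def __post_init__(self) -> None:
        if self.eta < 1 or self.tau < 1 or self.total_rounds < 1:
            raise ValueError("eta, tau and total_rounds must be >= 1")
        if self.thread_profiles is not None and len(self.thread_profiles) != self.eta:
            raise ValueError("need exactly eta thread profiles")
        if self.seeds is not None and len(self.seeds) != self.eta:
            raise ValueError("need exactly eta seeds")


def make_profiles(eta: int, base, solver_kind: str) -> list:
    """η option sets interpolating conservative -> aggressive.

    eSS: the RefSet size shrinks and the local-search cadence quickens from
    the first (most conservative) to the last (most aggressive) profile.
    VNS: the neighborhood cap shrinks and the upper half of the profiles
    switches to aggressive single-sweep descent.  With η = 1 the base
    options are returned unchanged.
    """
    if eta < 1:
        raise ValueError("eta must be >= 1")
    if eta == 1:
        return [base]
    profiles = []
    for r in np.linspace(0.0, 1.0, eta):  # r = 0 conservative ... 1 aggressive
        opts = type(base)(**base.__dict__)
        if solver_kind == "ess":
            n0 = opts.N if opts.N is not None else 20
            n = max(4, int(round(n0 * (1.5 - r))))
            opts.N = n + (n % 2)
            opts.local_search_interval = max(1, int(round(opts.local_search_interval * (2.0 - 1.8 * r))))
            opts.stagnation_threshold = max(2, int(round(opts.stagnation_threshold * (2.0 - 1.5 * r))))
        elif solver_kind == "vns":
            if opts.k_max is not None:
                opts.k_max = max(1, int(round(opts.k_max * (1.0 - 0.7 * r))))
            opts.aggressive = bool(r > 0.5)
        else:
            raise ValueError(f"unknown solver kind {solver_kind!r}")
        profiles.append(opts)
    # guarantee strictly decreasing eSS population sizes across profiles
    if solver_kind == "ess":
        for i in range(1, eta):
            if profiles[i].N >= profiles[i - 1].N:
                profiles[i].N = max(4, profiles[i - 1].N - 2)
    return profiles


def cooperative_solve(
    problem: OptimizationProblem,
    config: CooperationConfig,
    solver_kind: str = "ess",
) -> SolverResult:
    """Run η cooperating solver threads in synchronous evaluation rounds.

    Returns the global best; per-thread histories and bests are attached
    under ``metadata["threads"]``.  With η = 1 the run is identical to the
    plain solver with the same seed and budget, since a thread's own best is
    never broadcast back to itself.
    """
    if solver_kind not in ("ess", "vns"):
        raise ValueError("solver_kind must be 'ess' or 'vns'")
    cls, opt_cls = (ESS, ESSOptions) if solver_kind == "ess" else (VNS, VNSOptions)
    base = config.base_options if config.base_options is not None else opt_cls()
    profiles = config.thread_profiles or make_profiles(config.eta, base, solver_kind)
    if config.seeds is not None:
        seeds = config.seeds
    elif config.eta == 1:
        seeds = [base.seed]
    else:
        seeds = [((base.seed or 0) * 1009 + 101 * t + 1) % (2**31) for t in range(config.eta)]
    budget = config.tau * config.total_rounds
    threads = []
    for t in range(config.eta):
        opts = type(profiles[t])(**profiles[t].__dict__)
        opts.max_evaluations = budget
        opts.seed = seeds[t]
        threads.append(cls(problem, opts))

    round_bests: list[float] = []
    for rnd in range(1, config.total_rounds + 1):
        target = config.tau * rnd
        for th in threads:
            th.run_until(target)
        # exchange: broadcast the round's global best to every *other* thread
        origin = min(range(config.eta), key=lambda t: threads[t].best.penalized)
        best_sol = threads[origin].best
        for t, th in enumerate(threads):
            if t == origin:
                continue
            th.inject(best_sol)
            if config.share_refset and solver_kind == "ess":
                donors = sorted(threads[origin].refset, key=lambda s: s.penalized)
                if len(donors) > 1:
                    th.inject(donors[1])
        round_bests.append(best_sol.penalized)

    results = [th.result() for th in threads]
    origin = int(np.argmin([r.best.penalized for r in results]))
    merged: list[tuple[int, float]] = []
    best_so_far = math.inf
    events = sorted((c, v) for r in results for c, v in r.history)
    for c, v in events:
        if v < best_so_far:
            best_so_far = v
            merged.append((c, v))
    return SolverResult(
        best=results[origin].best,
        history=merged,
        total_evaluations=sum(r.total_evaluations for r in results),
        seed=None,
        metadata={
            "solver": f"cooperative-{solver_kind}",
            "eta": config.eta,
            "tau": config.tau,
            "round_bests": round_bests,
            "seeds": list(seeds),
            "threads": [
                {"best": r.best, "history": r.history, "total_evaluations": r.total_evaluations,
                 "seed": r.seed, "options": r.metadata.get("options")}
                for r in results
            ],
        },
    )
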