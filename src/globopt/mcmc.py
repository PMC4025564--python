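"""Multi-start Metropolis–Hastings sampling of parameter posteriors.

Parameter estimation by Bayesian inference: rather than a single best-fit
vector, the sampler returns draws from the full posterior, so experimental
error and structural non-identifiability show up directly as spread,
multimodality or covariation in the marginal distributions.

Several independent chains are launched from distinct uniform starting
points inside the bounding box (a multi-start scheme: multimodal posteriors
are covered even when single chains mix slowly).  Each chain is a Gaussian
random walk whose per-parameter step sizes adapt multiplicatively during the
burn-in phase toward a 0.2–0.45 acceptance band and are frozen afterwards,
so the retained samples come from a valid fixed-kernel Metropolis–Hastings
chain.  Proposals falling outside the box are rejected, which is equivalent
to a uniform-prior indicator.  The number of visits to a region is then
proportional to its posterior probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .problem import Solution

__all__ = [
    "PosteriorProblem",
    "MCMCChain",
    "metropolis_accept",
    "bayesfit_sample",
    "marginal_summary",
    "pairwise_covariation",
]

QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass
class PosteriorProblem:
    """Log-likelihood + log-prior over a continuous box.

    The default prior is uniform over the bounds (log-prior 0 inside,
    −inf outside; the normalization constant is irrelevant to sampling).
    """

    log_likelihood: Callable
    lower: np.ndarray
    upper: np.ndarray
    log_prior: Callable | None = None

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or np.any(self.lower > self.upper):
            raise ValueError("invalid bounds")

    @property
    def nvar(self) -> int:
        return self.lower.size

    def log_posterior(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lower) or np.any(x > self.upper):
            return -math.inf
        lp = 0.0 if self.log_prior is None else float(self.log_prior(x))
        if not math.isfinite(lp):
            return -math.inf
        ll = float(self.log_likelihood(x))
        return ll + lp if math.isfinite(ll) else -math.inf


@dataclass
class MCMCChain:
    """Post-burn-in samples of one chain with acceptance bookkeeping."""

    samples: np.ndarray          # (n_retained, nvar)
    log_posteriors: np.ndarray   # (n_retained,)
    proposal_scales: np.ndarray  # frozen post-adaptation step sizes
    accepted_count: int
    n_proposals: int
    start_index: int

    @property
    def acceptance_rate(self) -> float:
        return self.accepted_count / max(self.n_proposals, 1)


def metropolis_accept(logp_current: float, logp_proposal: float, u: float) -> bool:
    """Metropolis–Hastings criterion: accept iff u < min(1, posterior ratio)."""
    if logp_proposal == -math.inf:
        return False
    return u < math.exp(min(0.0, logp_proposal - logp_current))


def bayesfit_sample(
    problem: PosteriorProblem,
    n_starts: int = 4,
    steps_per_chain: int = 10_000,
    burn_in_fraction: float = 0.5,
    seed: int | None = None,
    initial_scale_fraction: float = 0.05,
    adapt_window: int = 50,
    acceptance_band: tuple[float, float] = (0.2, 0.45),
) -> tuple[list[MCMCChain], Solution]:
    """Run ``n_starts`` adaptive random-walk chains; return chains + best fit.

    Starting points are drawn uniformly in the box and must have posterior
    support (after 100·nvar failed draws a ``RuntimeError`` is raised).
    Per-parameter proposal scales start at ``initial_scale_fraction`` of the
    bound width and are rescaled by ×1.1 / ÷1.1 per ``adapt_window`` steps
    whenever the window acceptance rate leaves ``acceptance_band`` — during
    burn-in only.  The best fit is the highest log-posterior point seen
    anywhere, burn-in included.
    """
    if n_starts < 1 or steps_per_chain < 1:
        raise ValueError("n_starts and steps_per_chain must be >= 1")
    rng = np.random.default_rng(seed)
    nvar = problem.nvar
    width = problem.upper - problem.lower
    n_burn = int(steps_per_chain * burn_in_fraction)

    chains: list[MCMCChain] = []
    best_x, best_lp = None, -math.inf
    for c in range(n_starts):
        # find a supported start
        x = lp = None
        for _ in range(100 * nvar):
            cand = rng.uniform(problem.lower, problem.upper)
            lp_c = problem.log_posterior(cand)
            if lp_c > -math.inf:
                x, lp = cand, lp_c
                break
        if x is None:
            raise RuntimeError("no support found: posterior is -inf at every tried start")
        if lp > best_lp:
            best_x, best_lp = x.copy(), lp
        scales = initial_scale_fraction * np.where(width > 0, width, 1.0)
        kept_x, kept_lp = [], []
        accepted = 0
        window_accepted = 0
        for step in range(1, steps_per_chain + 1):
            prop = x + rng.normal(size=nvar) * scales
            lp_prop = problem.log_posterior(prop)
            if metropolis_accept(lp, lp_prop, rng.uniform()):
                x, lp = prop, lp_prop
                accepted += 1
                window_accepted += 1
            if lp > best_lp:
                best_x, best_lp = x.copy(), lp
            if step <= n_burn and step % adapt_window == 0:
                rate = window_accepted / adapt_window
                if rate < acceptance_band[0]:
                    scales = scales / 1.1
                elif rate > acceptance_band[1]:
                    scales = scales * 1.1
                window_accepted = 0
            if step > n_burn:
                kept_x.append(x.copy())
                kept_lp.append(lp)
        chains.append(MCMCChain(
            samples=np.asarray(kept_x).reshape(len(kept_x), nvar),
            log_posteriors=np.asarray(kept_lp, dtype=float),
            proposal_scales=scales,
            accepted_count=accepted,
            n_proposals=steps_per_chain,
            start_index=c,
        ))
    best_fit = Solution(x=best_x, f=-best_lp, violation=0.0, penalized=-best_lp)
    return chains, best_fit


def _pooled(chains: Sequence[MCMCChain]) -> np.ndarray:
    arrays = [c.samples for c in chains if c.samples.size]
    if not arrays:
        raise ValueError("no retained samples in any chain")
    return np.concatenate(arrays, axis=0)


def marginal_summary(
    chains: Sequence[MCMCChain],
    index: int,
    bounds: tuple[float, float],
    n_bins: int = 30,
    best_fit: Solution | None = None,
) -> dict:
    """Pooled histogram + quantiles of one parameter's marginal posterior.

    Bin edges span the parameter's bounds; quantiles (2.5/25/50/75/97.5%)
    come from the pooled empirical distribution.  A multimodal histogram is
    the practical signature of non-identifiability.
    """
    pooled = _pooled(chains)[:, index]
    counts, edges = np.histogram(pooled, bins=n_bins, range=bounds)
    qs = np.quantile(pooled, QUANTILES)
    return {
        "counts": counts,
        "edges": edges,
        "quantiles": dict(zip((f"q{100 * q:g}" for q in QUANTILES), qs.tolist())),
        "mean": float(pooled.mean()),
        "best_fit": None if best_fit is None else float(best_fit.x[index]),
        "n_samples": pooled.size,
    }


def pairwise_covariation(
    chains: Sequence[MCMCChain],
    i: int,
    j: int,
    bounds_i: tuple[float, float],
    bounds_j: tuple[float, float],
    n_bins: int = 30,
) -> dict:
    """Pooled 2-D histogram of parameters i and j on the bounds rectangle.

    Its row/column sums equal the corresponding 1-D marginal histograms, so
    joint and marginal views stay mutually consistent.  Correlated ridges in
    this histogram reveal parameter covariation (sloppy directions).
    """
    if i == j:
        raise ValueError("pairwise covariation needs two distinct parameters")
    pooled = _pooled(chains)
    counts, xedges, yedges = np.histogram2d(
        pooled[:, i], pooled[:, j], bins=n_bins, range=[bounds_i, bounds_j]
    )
    return {"counts": counts, "xedges": xedges, "yedges": yedges}
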