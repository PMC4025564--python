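"""Metabolic engineering by gene knockout with a flux-balance inner LP.

Flux balance analysis (FBA) treats the metabolic network as a stoichiometric
matrix S at steady state (S v = 0, lb <= v <= ub) and assumes the cell
optimizes a biological objective — here biomass maximization.  The strain
design question is which gene knockouts reroute flux so that a metabolite
of interest (a succinate analogue) is produced at the growth optimum.

The design problem is encoded with a fixed number of integer knockout
slots: each decision variable ranges over 0 (no knockout) to the number of
genes; repeated gene picks are filtered inside the objective, so the
encoding is insensitive to slot order and duplicates.  The objective value
is the negative target-metabolite flux at the biomass optimum; degenerate
flux optima are resolved by a secondary LP that maximizes the target flux
at fixed optimal biomass, making the black box deterministic.  Infeasible
or zero-growth knockout sets score 0 (no production credit).

The bundled toy model is a *synthetic* central-carbon sketch (fixed glucose
uptake, glycolysis producing precursor/redox/energy, a biomass sink, and
competing redox-balancing fermentation routes); its 52-gene map is
many-to-one with exactly three flux-routing genes, so the exact optimum is
enumerable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from ..problem import OptimizationProblem

__all__ = [
    "MetabolicToyModel",
    "toy_core_model",
    "write_toy_model",
    "read_toy_model",
    "fba_optimum",
    "fba_knockout_objective",
    "make_knockout_problem",
    "enumerate_knockouts",
    "N_GENES",
    "N_SLOTS",
]

N_GENES = 52
N_SLOTS = 5
_GROWTH_TOL = 1e-9


@dataclass
class MetabolicToyModel:
    """Tabular steady-state metabolic model.

    ``stoichiometry`` is metabolites × reactions; ``gene_to_reactions``
    maps gene id (1-based) to the reaction indices it catalyzes (knocking
    out the gene closes those reactions).
    """

    metabolites: list[str]
    reactions: list[str]
    stoichiometry: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    biomass_index: int
    target_index: int
    gene_to_reactions: dict[int, list[int]]

    def __post_init__(self) -> None:
        m, n = self.stoichiometry.shape
        if m != len(self.metabolites) or n != len(self.reactions):
            raise ValueError("stoichiometric matrix shape mismatch")
        if not (np.all(np.isfinite(self.lb)) and np.all(np.isfinite(self.ub))):
            raise ValueError("flux bounds must be finite")

    @property
    def n_genes(self) -> int:
        return max(self.gene_to_reactions) if self.gene_to_reactions else 0


def toy_core_model(n_genes: int = N_GENES) -> MetabolicToyModel:
    """Synthetic central-carbon toy model with an enumerable knockout optimum.

    Internal metabolites: A (sugar), P (precursor), N (redox carrier),
    T (energy carrier).  Reactions (exported products untracked):

    ==========  =============================  =====================
    uptake      -> A                           fixed at 10
    glycolysis  A -> 2 P + 2 N + 2 T
    biomass     P + 2 T ->                     objective
    lactate     P + N ->                       redox sink 1
    ethanol_a   P + 2 N ->                     redox sink 2 (isozyme a)
    ethanol_b   P + 2 N ->                     redox sink 2 (isozyme b)
    succinate   P + 2 N + T ->                 target product
    atp_leak    T ->                           maintenance slack
    ==========  =============================  =====================

    Redox balance forces fermentation; energy stringency keeps the target
    route closed until *both* ethanol isozymes are knocked out, so the best
    knockout set is {ethanol_a, ethanol_b} (target flux 20/3).  Genes 1-3
    map to lactate/ethanol_a/ethanol_b; genes 4-10 to essential reactions
    (their knockout abolishes growth); the rest to the maintenance leak
    (silent).
    """
    metabolites = ["A", "P", "N", "T"]
    reactions = ["uptake", "glycolysis", "biomass", "lactate",
                 "ethanol_a", "ethanol_b", "succinate", "atp_leak"]
    S = np.array([
        #  upt  gly  bio  lac  etA  etB  suc  leak
        [1.0, -1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # A
        [0.0, 2.0, -1.0, -1.0, -1.0, -1.0, -1.0, 0.0],  # P
        [0.0, 2.0, 0.0, -1.0, -2.0, -2.0, -2.0, 0.0],   # N
        [0.0, 2.0, -2.0, 0.0, 0.0, 0.0, -1.0, -1.0],    # T
    ])
    lb = np.array([10.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    ub = np.array([10.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0])
    gene_map: dict[int, list[int]] = {}
    routing = {1: [3], 2: [4], 3: [5]}            # lactate, ethanol_a, ethanol_b
    essential = {4: [0], 5: [1], 6: [2], 7: [0], 8: [1], 9: [2], 10: [0]}
    for g in range(1, n_genes + 1):
        if g in routing:
            gene_map[g] = routing[g]
        elif g in essential:
            gene_map[g] = essential[g]
        else:
            gene_map[g] = [7]  # maintenance leak: knockout is silent
    return MetabolicToyModel(
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=S,
        lb=lb,
        ub=ub,
        biomass_index=2,
        target_index=6,
        gene_to_reactions=gene_map,
    )


def write_toy_model(model: MetabolicToyModel, outdir: str | Path) -> tuple[Path, Path]:
    """Write the model as a CSV pair (reactions + gene map)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, rxn in enumerate(model.reactions):
        stoich = ",".join(
            f"{met}:{model.stoichiometry[i, j]:g}"
            for i, met in enumerate(model.metabolites)
            if model.stoichiometry[i, j] != 0
        )
        role = "biomass" if j == model.biomass_index else "target" if j == model.target_index else ""
        rows.append({"reaction": rxn, "stoichiometry": stoich,
                     "lb": model.lb[j], "ub": model.ub[j], "role": role})
    reactions_path = outdir / "reactions.csv"
    pd.DataFrame(rows).to_csv(reactions_path, index=False)
    gene_rows = [
        {"gene": g, "reactions": ";".join(model.reactions[j] for j in rxns)}
        for g, rxns in sorted(model.gene_to_reactions.items())
    ]
    genes_path = outdir / "gene_map.csv"
    pd.DataFrame(gene_rows).to_csv(genes_path, index=False)
    return reactions_path, genes_path


def read_toy_model(reactions_csv: str | Path, genes_csv: str | Path) -> MetabolicToyModel:
    """Load a model written by :func:`write_toy_model`."""
    rx = pd.read_csv(reactions_csv).fillna({"role": "", "stoichiometry": ""})
    reactions = rx["reaction"].tolist()
    mets: list[str] = []
    coeffs = []
    for s in rx["stoichiometry"]:
        d = {}
        if isinstance(s, str) and s:
            for part in s.split(","):
                met, c = part.split(":")
                d[met] = float(c)
                if met not in mets:
                    mets.append(met)
        coeffs.append(d)
    S = np.zeros((len(mets), len(reactions)))
    for j, d in enumerate(coeffs):
        for met, c in d.items():
            S[mets.index(met), j] = c
    roles = rx["role"].tolist()
    gm = pd.read_csv(genes_csv)
    gene_map = {
        int(row.gene): [reactions.index(r) for r in str(row.reactions).split(";") if r]
        for row in gm.itertuples()
    }
    return MetabolicToyModel(
        metabolites=mets,
        reactions=reactions,
        stoichiometry=S,
        lb=rx["lb"].to_numpy(float),
        ub=rx["ub"].to_numpy(float),
        biomass_index=roles.index("biomass"),
        target_index=roles.index("target"),
        gene_to_reactions=gene_map,
    )


def fba_optimum(
    model: MetabolicToyModel,
    closed_reactions: frozenset[int] = frozenset(),
) -> tuple[float, float] | None:
    """Biomass-optimal FBA with deterministic target tie-breaking.

    Returns ``(biomass, target_flux)`` at the growth optimum, where the
    target flux is itself maximized over the biomass-optimal face by a
    secondary LP.  Returns ``None`` when the LP is infeasible.
    """
    lb = model.lb.copy()
    ub = model.ub.copy()
    for j in closed_reactions:
        lb[j] = 0.0
        ub[j] = 0.0
        if model.lb[j] > 0:  # a forced flux cannot be closed feasibly
            return None
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.biomass_index] = -1.0
    res = linprog(c, A_eq=model.stoichiometry, b_eq=np.zeros(len(model.metabolites)),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return None
    biomass = -res.fun
    # secondary LP: maximize target flux holding biomass at its optimum
    lb2 = lb.copy()
    lb2[model.biomass_index] = biomass * (1.0 - 1e-9)
    c2 = np.zeros(n)
    c2[model.target_index] = -1.0
    res2 = linprog(c2, A_eq=model.stoichiometry, b_eq=np.zeros(len(model.metabolites)),
                   bounds=list(zip(lb2, ub)), method="highs")
    if not res2.success:
        return biomass, float(res.x[model.target_index])
    return biomass, -res2.fun


def _ko_to_reactions(model: MetabolicToyModel, ko: np.ndarray) -> frozenset[int]:
    genes = {int(round(g)) for g in ko if round(g) != 0}  # duplicate KOs filtered
    closed: set[int] = set()
    for g in genes:
        closed.update(model.gene_to_reactions.get(g, ()))
    return frozenset(closed)


def fba_knockout_objective(
    model: MetabolicToyModel,
    ko: np.ndarray,
    cache: dict | None = None,
) -> float:
    """Negative target flux at the biomass optimum for a knockout vector.

    ``ko`` holds :data:`N_SLOTS` integers in [0, n_genes]; 0 means the slot
    is unused and duplicate gene picks collapse to one.  Infeasible or
    zero-growth designs return 0.  ``cache`` (keyed by the closed reaction
    set) skips repeated LP solves across equivalent encodings.
    """
    ko = np.asarray(ko, float)
    if np.any(ko < 0) or np.any(ko > model.n_genes):
        raise ValueError(f"knockout entries must lie in [0, {model.n_genes}]")
    closed = _ko_to_reactions(model, ko)
    if cache is not None and closed in cache:
        return cache[closed]
    opt = fba_optimum(model, closed)
    if opt is None or opt[0] <= _GROWTH_TOL:
        value = 0.0
    else:
        value = -opt[1]
    if cache is not None:
        cache[closed] = value
    return value


def make_knockout_problem(model: MetabolicToyModel, n_slots: int = N_SLOTS) -> OptimizationProblem:
    """Integer knockout-design problem over ``n_slots`` gene slots."""
    cache: dict = {}
    return OptimizationProblem(
        objective=lambda x: fba_knockout_objective(model, x, cache),
        lower=np.zeros(n_slots),
        upper=np.full(n_slots, float(model.n_genes)),
        integer_indices=frozenset(range(n_slots)),
        name="fba_knockout",
    )


def enumerate_knockouts(model: MetabolicToyModel, max_size: int = 3) -> tuple[float, frozenset[int]]:
    """Brute-force best objective over all gene sets of size <= max_size.

    Enumerates *reaction-level* knockout patterns (the gene map is
    many-to-one, so distinct gene sets often close identical reaction sets
    and one LP serves them all), then reports the best value with a
    witnessing gene set.
    """
    import itertools

    genes = list(range(1, model.n_genes + 1))
    cache: dict = {}
    best_val, best_set = np.inf, frozenset()
    for k in range(0, max_size + 1):
        for combo in itertools.combinations(genes, k):
            ko = np.zeros(N_SLOTS)
            ko[:k] = combo
            v = fba_knockout_objective(model, ko, cache)
            if v < best_val:
                best_val, best_set = v, frozenset(combo)
    return float(best_val), best_set
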