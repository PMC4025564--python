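"""Training of Boolean logic models of signaling networks.

A prior-knowledge network is a signed directed graph: nodes are (typically)
proteins, edges carry a sign (activating or inhibitory).  From the graph one
builds a hypergraph of candidate gates: every combination of edges arriving
at a node up to a fan-in limit becomes a *hyperedge* — a multi-input
hyperedge is an AND gate, while OR gates arise implicitly because several
selected single-input hyperedges into the same node combine disjunctively.

A model is a binary selection vector P over the r candidate hyperedges.
Given an experimental condition (stimuli on/off, inhibited nodes clamped),
the model's prediction is its logical steady state: synchronous Boolean
updates iterated to a fixed point.  The training score balances data fit
against model size,

    theta(P) = theta_f(P) + alpha * theta_s(P),

where theta_f is the mean squared error between predicted Boolean readouts
B^M in {0,1} and measured values B^E in [0,1), and theta_s penalizes each
selected hyperedge proportionally to its number of inputs (a 3-input AND
gate costs three times a single edge), normalized by the total input count
v_es over all candidates.  Minimizing theta over P is an integer program
solved here with VNS.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..problem import OptimizationProblem

__all__ = [
    "Hyperedge",
    "LogicModel",
    "LogicData",
    "read_sif",
    "expand_hyperedges",
    "logic_steady_state",
    "logic_objective",
    "make_logic_ip_problem",
]

UNDEFINED = -1  # steady-state value of a non-converging node


@dataclass(frozen=True)
class Hyperedge:
    """Inputs ((node, sign), ...) with sign in {+1, -1}, one output node.

    A single-input hyperedge is a plain signed edge; multi-input hyperedges
    AND their inputs (a -1 input enters negated).
    """

    inputs: tuple[tuple[str, int], ...]
    output: str

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    def __str__(self) -> str:
        lhs = "+".join(("!" if s < 0 else "") + n for n, s in self.inputs)
        return f"{lhs}->{self.output}"


@dataclass
class LogicModel:
    """Candidate hypergraph over named nodes.

    ``stimuli`` are experimentally controlled inputs, ``inhibitible`` nodes
    can be clamped to 0 by an inhibitor, ``readouts`` are measured.
    """

    nodes: list[str]
    hyperedges: list[Hyperedge]
    stimuli: list[str] = field(default_factory=list)
    inhibitible: list[str] = field(default_factory=list)
    readouts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for e in self.hyperedges:
            if e.output not in known or any(n not in known for n, _ in e.inputs):
                raise ValueError(f"hyperedge {e} references unknown node")
            if e.n_inputs < 1:
                raise ValueError("hyperedge needs at least one input")

    @property
    def r(self) -> int:
        return len(self.hyperedges)

    @property
    def v_es(self) -> int:
        """Total input count over all candidate hyperedges (Σ v_e)."""
        return sum(e.n_inputs for e in self.hyperedges)


@dataclass
class LogicData:
    """Experimental cube: conditions × readouts × time points.

    ``conditions`` is a list of dicts with keys ``stimuli`` (name -> 0/1)
    and ``inhibitors`` (names clamped to 0).  ``measurements`` maps
    (condition index, readout, time) to a value in [0, 1); missing entries
    are simply absent.
    """

    conditions: list[dict]
    measurements: dict[tuple[int, str, float], float]

    def __post_init__(self) -> None:
        for v in self.measurements.values():
            if not (0.0 <= v < 1.0):
                raise ValueError("data values must lie in [0, 1)")

    @property
    def n_points(self) -> int:
        return len(self.measurements)


def read_sif(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a SIF network: tab/whitespace separated ``source sign target``
    triples with sign 1 (activating) or -1 (inhibitory)."""
    edges = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed SIF line: {raw!r}")
        src, rel, dst = parts
        sign = int(rel)
        if sign not in (1, -1):
            raise ValueError(f"SIF relationship must be 1 or -1, got {rel!r}")
        edges.append((src, sign, dst))
    return edges


def expand_hyperedges(
    edges: list[tuple[str, int, str]],
    max_fan_in: int = 4,
) -> list[Hyperedge]:
    """All AND combinations of the edges arriving at each node, up to
    ``max_fan_in`` inputs.  Size-1 combinations are the original edges; a
    node with several incoming edges gets one candidate hyperedge per
    nonempty input subset."""
    incoming: dict[str, list[tuple[str, int]]] = {}
    for src, sign, dst in edges:
        incoming.setdefault(dst, []).append((src, sign))
    out: list[Hyperedge] = []
    for dst in sorted(incoming):
        inputs = sorted(set(incoming[dst]))
        for k in range(1, min(max_fan_in, len(inputs)) + 1):
            for combo in itertools.combinations(inputs, k):
                out.append(Hyperedge(inputs=tuple(combo), output=dst))
    return out


def logic_steady_state(
    model: LogicModel,
    selection: np.ndarray,
    condition: dict,
    max_sweeps: int | None = None,
) -> dict[str, int]:
    """Logical steady state of the selected sub-model under one condition.

    Synchronous update: each node's next value is the OR over its selected
    incoming hyperedges of the AND over inputs (a -1 input contributes the
    negation).  Stimuli are clamped to their set value, inhibited nodes to
    0, everything else starts at 0.  Iteration stops at a fixed point or
    after ``2 * len(nodes)`` sweeps; nodes still changing in the last sweep
    are flagged :data:`UNDEFINED` — oscillatory, no steady state.
    """
    selection = np.asarray(selection)
    if selection.size != model.r:
        raise ValueError("selection length must equal the number of hyperedges")
    stimuli = dict(condition.get("stimuli", {}))
    inhibited = set(condition.get("inhibitors", ()))
    max_sweeps = max_sweeps or 2 * len(model.nodes)

    selected = [e for e, p in zip(model.hyperedges, selection) if p]
    by_output: dict[str, list[Hyperedge]] = {}
    for e in selected:
        by_output.setdefault(e.output, []).append(e)

    def clamp(state: dict[str, int]) -> None:
        for s, v in stimuli.items():
            state[s] = int(v)
        for n in inhibited:
            state[n] = 0

    state = {n: 0 for n in model.nodes}
    clamp(state)
    prev = None
    for _ in range(max_sweeps):
        nxt = {}
        for n in model.nodes:
            gates = by_output.get(n, [])
            val = 0
            for g in gates:
                v = 1
                for inp, sign in g.inputs:
                    x = state[inp]
                    v &= (1 - x) if sign < 0 else x
                    if not v:
                        break
                val |= v
                if val:
                    break
            nxt[n] = val if gates else state[n] if n in stimuli else 0
        clamp(nxt)
        prev, state = state, nxt
        if prev == state:
            return state
    # no fixed point: flag the nodes still oscillating
    return {n: (state[n] if state[n] == prev[n] else UNDEFINED) for n in model.nodes}


def logic_objective(
    model: LogicModel,
    selection: np.ndarray,
    data: LogicData,
    alpha: float,
) -> tuple[float, float, float]:
    """Training score theta = theta_f + alpha * theta_s and its components.

    theta_f is the mean squared residual over the defined data points; an
    UNDEFINED prediction contributes the worst-case residual 1.  theta_s is
    (1/v_es) * sum of v_e over selected hyperedges e.
    """
    if data.n_points == 0:
        raise ValueError("no data points defined")
    selection = np.asarray(selection)
    sse = 0.0
    states = [logic_steady_state(model, selection, cond) for cond in data.conditions]
    for (k, readout, _t), b_e in data.measurements.items():
        b_m = states[k][readout]
        sse += 1.0 if b_m == UNDEFINED else (b_m - b_e) ** 2
    theta_f = sse / data.n_points
    v_es = model.v_es
    theta_s = sum(e.n_inputs for e, p in zip(model.hyperedges, selection) if p) / v_es if v_es else 0.0
    return theta_f + alpha * theta_s, theta_f, theta_s


def make_logic_ip_problem(
    model: LogicModel,
    data: LogicData,
    alpha: float = 1e-4,
) -> OptimizationProblem:
    """Wrap the training score as a binary integer program over P for VNS."""

    def objective(x: np.ndarray) -> float:
        theta, _f, _s = logic_objective(model, np.round(x).astype(int), data, alpha)
        return theta

    return OptimizationProblem(
        objective=objective,
        lower=np.zeros(model.r),
        upper=np.ones(model.r),
        integer_indices=frozenset(range(model.r)),
        name="logic_training",
    )
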