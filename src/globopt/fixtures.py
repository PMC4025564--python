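"""Synthetic test-problem generators with recorded ground truth.

Every case study ships as a generator rather than a data file: a seeded
generator builds the network/model/data-set, *computes* the true optimum by
an exhaustive or closed-form oracle, and records it in a sidecar JSON file,
so solver tests can always check recovery against an independent answer.

Three kinds are provided:

``logic``
    A small signed signaling network (8 nodes) whose hyperedge expansion
    yields 10 candidate gates; quasi-steady-state measurements are simulated
    from a known sub-selection under all stimulus/inhibitor combinations,
    with additive Gaussian noise truncated into [0, 1).
``metabolic``
    The synthetic central-carbon knockout model (see
    :mod:`globopt.applications.fba`), written as a CSV pair, with the
    brute-force best knockout recorded.
``posterior``
    A Hill transfer-function curve fit, the building block of logic-ODE
    models: y = x^n / (x^n + k^n) with Gaussian measurement noise, known
    generating shape parameters (n, k) and known noise level.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .applications.fba import enumerate_knockouts, toy_core_model, write_toy_model
from .applications.logic import (
    Hyperedge,
    LogicData,
    LogicModel,
    expand_hyperedges,
    logic_objective,
    logic_steady_state,
    read_sif,
)
from .mcmc import PosteriorProblem

__all__ = [
    "make_logic_fixture",
    "make_posterior_fixture",
    "generate_fixture",
    "load_logic_fixture",
    "load_posterior_fixture",
    "enumerate_logic_selections",
]

_LOGIC_EDGES = [
    ("S1", 1, "A"),
    ("S2", 1, "B"),
    ("A", 1, "C"),
    ("B", 1, "C"),
    ("C", 1, "D"),
    ("B", 1, "E"),
    ("D", -1, "E"),
    ("C", 1, "F"),
]
_LOGIC_ALPHA = 0.01
_LOGIC_NOISE_SD = 0.05


def _logic_model() -> LogicModel:
    hyperedges = expand_hyperedges(_LOGIC_EDGES, max_fan_in=4)
    nodes = sorted({n for e in _LOGIC_EDGES for n in (e[0], e[2])})
    return LogicModel(
        nodes=nodes,
        hyperedges=hyperedges,
        stimuli=["S1", "S2"],
        inhibitible=["B"],
        readouts=["C", "D", "E", "F"],
    )


def _generating_selection(model: LogicModel) -> np.ndarray:
    sel = np.zeros(model.r, dtype=int)
    wanted = {(e_in, out) for e_in, out in
              [((("S1", 1),), "A"), ((("S2", 1),), "B"),
               ((("A", 1), ("B", 1)), "C"), ((("C", 1),), "D"),
               ((("D", -1),), "E"), ((("C", 1),), "F")]}
    for i, e in enumerate(model.hyperedges):
        if (tuple(sorted(e.inputs)), e.output) in {(tuple(sorted(w[0])), w[1]) for w in wanted}:
            sel[i] = 1
    return sel


def _logic_conditions() -> list[dict]:
    conds = []
    for s1, s2, inh in itertools.product((0, 1), (0, 1), (False, True)):
        conds.append({
            "stimuli": {"S1": s1, "S2": s2},
            "inhibitors": ["B"] if inh else [],
        })
    return conds


def make_logic_fixture(seed: int = 0) -> tuple[LogicModel, LogicData, float, np.ndarray]:
    """In-memory logic fixture: (model, data, alpha, generating selection)."""
    rng = np.random.default_rng(seed)
    model = _logic_model()
    sel = _generating_selection(model)
    conditions = _logic_conditions()
    t = 10.0  # nominal quasi-steady-state sampling time
    measurements: dict[tuple[int, str, float], float] = {}
    for k, cond in enumerate(conditions):
        state = logic_steady_state(model, sel, cond)
        for readout in model.readouts:
            noisy = state[readout] + rng.normal(0.0, _LOGIC_NOISE_SD)
            measurements[(k, readout, t)] = float(np.clip(noisy, 0.0, 1.0 - 1e-9))
    return model, LogicData(conditions=conditions, measurements=measurements), _LOGIC_ALPHA, sel


def enumerate_logic_selections(
    model: LogicModel, data: LogicData, alpha: float
) -> tuple[float, np.ndarray]:
    """Exhaustive oracle: best theta over all 2^r hyperedge selections."""
    best_theta, best_sel = np.inf, None
    for bits in itertools.product((0, 1), repeat=model.r):
        sel = np.array(bits)
        theta, _f, _s = logic_objective(model, sel, data, alpha)
        if theta < best_theta:
            best_theta, best_sel = theta, sel
    return float(best_theta), best_sel


# -- posterior fixture ---------------------------------------------------

_HILL_TRUE = {"n": 3.0, "k": 0.5}
_HILL_SIGMA = 0.05
_HILL_BOUNDS = {"lower": [0.5, 0.05], "upper": [8.0, 1.0]}


def _hill(x: np.ndarray, n: float, k: float) -> np.ndarray:
    return x**n / (x**n + k**n)


def make_posterior_fixture(seed: int = 0, n_points: int = 25):
    """Hill curve-fit posterior: returns (PosteriorProblem, truth dict, data).

    The two parameters control the transfer-function shape: ``n`` the
    steepness (Hill coefficient) and ``k`` the half-activation threshold.
    The likelihood is Gaussian with the known noise level.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.02, 1.0, n_points)
    y = _hill(x, _HILL_TRUE["n"], _HILL_TRUE["k"]) + rng.normal(0.0, _HILL_SIGMA, size=n_points)

    def log_likelihood(theta: np.ndarray) -> float:
        resid = y - _hill(x, theta[0], theta[1])
        return float(-0.5 * np.sum(resid**2) / _HILL_SIGMA**2)

    problem = PosteriorProblem(
        log_likelihood=log_likelihood,
        lower=np.array(_HILL_BOUNDS["lower"]),
        upper=np.array(_HILL_BOUNDS["upper"]),
    )
    truth = dict(_HILL_TRUE, sigma=_HILL_SIGMA)
    return problem, truth, pd.DataFrame({"x": x, "y": y})


# -- file-based generation (CLI `fixtures` subcommand) -------------------


def generate_fixture(kind: str, seed: int, outdir: str | Path) -> dict:
    """Write fixture files + a ``ground_truth.json`` sidecar; returns truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "logic":
        model, data, alpha, sel = make_logic_fixture(seed)
        with open(outdir / "network.sif", "w") as fh:
            for src, sign, dst in _LOGIC_EDGES:
                fh.write(f"{src}\t{sign}\t{dst}\n")
        rows = [
            {"condition": k, "readout": readout, "time": t, "value": v}
            for (k, readout, t), v in sorted(data.measurements.items())
        ]
        pd.DataFrame(rows).to_csv(outdir / "data.csv", index=False)
        cond_rows = [
            {
                "condition": k,
                "stimuli": ";".join(f"{n}={v}" for n, v in sorted(c["stimuli"].items())),
                "inhibitors": ";".join(c["inhibitors"]),
            }
            for k, c in enumerate(data.conditions)
        ]
        pd.DataFrame(cond_rows).to_csv(outdir / "conditions.csv", index=False)
        theta, _f, _s = logic_objective(model, sel, data, alpha)
        truth = {
            "kind": "logic",
            "seed": seed,
            "alpha": alpha,
            "generating_selection": sel.tolist(),
            "hyperedges": [str(e) for e in model.hyperedges],
            "theta_at_truth": theta,
        }
    elif kind == "metabolic":
        model = toy_core_model()
        write_toy_model(model, outdir)
        best_val, best_set = enumerate_knockouts(model, max_size=3)
        truth = {
            "kind": "metabolic",
            "seed": seed,
            "best_objective": best_val,
            "best_knockout_genes": sorted(best_set),
        }
    elif kind == "posterior":
        problem, hill_truth, frame = make_posterior_fixture(seed)
        frame.to_csv(outdir / "data.csv", index=False)
        truth = {
            "kind": "posterior",
            "seed": seed,
            "true_parameters": {"n": hill_truth["n"], "k": hill_truth["k"]},
            "sigma": hill_truth["sigma"],
            "bounds": _HILL_BOUNDS,
        }
    else:
        raise ValueError(f"unknown fixture kind {kind!r} (logic|metabolic|posterior)")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth


def load_logic_fixture(fixture_dir: str | Path) -> tuple[LogicModel, LogicData, float]:
    """Re-load a written logic fixture from its SIF + CSV files."""
    fixture_dir = Path(fixture_dir)
    edges = read_sif(fixture_dir / "network.sif")
    hyperedges = expand_hyperedges(edges, max_fan_in=4)
    nodes = sorted({n for e in edges for n in (e[0], e[2])})
    data_df = pd.read_csv(fixture_dir / "data.csv")
    cond_df = pd.read_csv(fixture_dir / "conditions.csv").fillna("")
    conditions = []
    for row in cond_df.sort_values("condition").itertuples():
        stimuli = {}
        if row.stimuli:
            for part in str(row.stimuli).split(";"):
                name, v = part.split("=")
                stimuli[name] = int(v)
        inhibitors = [s for s in str(row.inhibitors).split(";") if s]
        conditions.append({"stimuli": stimuli, "inhibitors": inhibitors})
    measurements = {
        (int(r.condition), str(r.readout), float(r.time)): float(r.value)
        for r in data_df.itertuples()
    }
    readouts = sorted(data_df["readout"].unique())
    model = LogicModel(
        nodes=nodes,
        hyperedges=hyperedges,
        stimuli=sorted({n for c in conditions for n in c["stimuli"]}),
        inhibitible=sorted({n for c in conditions for n in c["inhibitors"]}),
        readouts=readouts,
    )
    sidecar = fixture_dir / "ground_truth.json"
    alpha = json.loads(sidecar.read_text())["alpha"] if sidecar.exists() else _LOGIC_ALPHA
    return model, LogicData(conditions=conditions, measurements=measurements), alpha


def load_posterior_fixture(fixture_dir: str | Path) -> PosteriorProblem:
    """Rebuild the Hill-fit posterior from a written data.csv + sidecar."""
    fixture_dir = Path(fixture_dir)
    frame = pd.read_csv(fixture_dir / "data.csv")
    truth = json.loads((fixture_dir / "ground_truth.json").read_text())
    x = frame["x"].to_numpy(float)
    y = frame["y"].to_numpy(float)
    sigma = float(truth["sigma"])

    def log_likelihood(theta: np.ndarray) -> float:
        resid = y - _hill(x, theta[0], theta[1])
        return float(-0.5 * np.sum(resid**2) / sigma**2)

    return PosteriorProblem(
        log_likelihood=log_likelihood,
        lower=np.array(truth["bounds"]["lower"]),
        upper=np.array(truth["bounds"]["upper"]),
    )
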