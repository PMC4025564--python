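import itertools

import numpy as np
import pytest

from globopt.applications.logic import (
    UNDEFINED,
    Hyperedge,
    LogicData,
    LogicModel,
    expand_hyperedges,
    logic_objective,
    logic_steady_state,
    make_logic_ip_problem,
)
from globopt.fixtures import enumerate_logic_selections, make_logic_fixture
from globopt.vns import VNSOptions, vns_solve


def chain_model():
    return LogicModel(
        nodes=["A", "B", "C"],
        hyperedges=[
            Hyperedge(((("A"), 1),), "B"),
            Hyperedge(((("B"), 1),), "C"),
        ],
        stimuli=["A"],
        readouts=["C"],
    )


class TestSteadyState:
    def test_forward_propagation_along_chain(self):
        state = logic_steady_state(chain_model(), [1, 1], {"stimuli": {"A": 1}})
        assert state["B"] == 1 and state["C"] == 1

    def test_inhibitory_edge_negates_input(self):
        model = LogicModel(
            nodes=["A", "B"],
            hyperedges=[Hyperedge((("A", -1),), "B")],
            stimuli=["A"],
        )
        assert logic_steady_state(model, [1], {"stimuli": {"A": 1}})["B"] == 0
        assert logic_steady_state(model, [1], {"stimuli": {"A": 0}})["B"] == 1

    def test_and_gate_versus_or_gates(self):
        nodes = ["A", "B", "C"]
        and_model = LogicModel(
            nodes=nodes, hyperedges=[Hyperedge((("A", 1), ("B", 1)), "C")], stimuli=["A", "B"]
        )
        or_model = LogicModel(
            nodes=nodes,
            hyperedges=[Hyperedge((("A", 1),), "C"), Hyperedge((("B", 1),), "C")],
            stimuli=["A", "B"],
        )
        cond = {"stimuli": {"A": 1, "B": 0}}
        assert logic_steady_state(and_model, [1], cond)["C"] == 0
        assert logic_steady_state(or_model, [1, 1], cond)["C"] == 1

    def test_inhibitor_clamps_node_to_zero(self):
        state = logic_steady_state(
            chain_model(), [1, 1], {"stimuli": {"A": 1}, "inhibitors": ["B"]}
        )
        assert state["B"] == 0 and state["C"] == 0

    def test_unselected_edges_do_not_fire(self):
        state = logic_steady_state(chain_model(), [0, 1], {"stimuli": {"A": 1}})
        assert state["B"] == 0 and state["C"] == 0

    def test_negative_feedback_loop_flagged_undefined(self):
        model = LogicModel(
            nodes=["S", "A", "B"],
            hyperedges=[
                Hyperedge((("S", 1), ("B", -1)), "A"),
                Hyperedge((("A", 1),), "B"),
            ],
            stimuli=["S"],
        )
        state = logic_steady_state(model, [1, 1], {"stimuli": {"S": 1}})
        assert UNDEFINED in (state["A"], state["B"])

    def test_fixed_point_is_idempotent(self):
        model, data, _alpha, sel = make_logic_fixture(0)
        for cond in data.conditions:
            state = logic_steady_state(model, sel, cond)
            again = logic_steady_state(model, sel, cond, max_sweeps=1000)
            assert state == again


class TestHyperedgeExpansion:
    def test_all_and_combinations_generated(self):
        edges = [("A", 1, "C"), ("B", 1, "C"), ("D", -1, "C")]
        out = expand_hyperedges(edges, max_fan_in=4)
        sizes = sorted(e.n_inputs for e in out)
        assert sizes == [1, 1, 1, 2, 2, 2, 3]  # 3 singles, 3 pairs, 1 triple

    def test_fan_in_cap_respected(self):
        edges = [(f"N{i}", 1, "C") for i in range(5)]
        out = expand_hyperedges(edges, max_fan_in=2)
        assert max(e.n_inputs for e in out) == 2


class TestObjective:
    def test_residual_arithmetic_single_point(self):
        model = chain_model()
        data = LogicData(
            conditions=[{"stimuli": {"A": 1}}],
            measurements={(0, "C", 0.0): 0.5},
        )
        theta, theta_f, theta_s = logic_objective(model, [1, 1], data, alpha=0.0)
        assert theta == pytest.approx((1 - 0.5) ** 2)

    def test_three_input_and_gate_penalized_three_times_a_single_edge(self):
        # one 3-input AND selected among candidates totalling v_es = 6 inputs
        model = LogicModel(
            nodes=["A", "B", "C", "D"],
            hyperedges=[
                Hyperedge((("A", 1), ("B", 1), ("C", 1)), "D"),
                Hyperedge((("A", 1),), "D"),
                Hyperedge((("B", 1),), "D"),
                Hyperedge((("C", 1),), "D"),
            ],
            stimuli=["A", "B", "C"],
        )
        assert model.v_es == 6
        data = LogicData(conditions=[{"stimuli": {"A": 0, "B": 0, "C": 0}}],
                         measurements={(0, "D", 0.0): 0.0})
        _theta, _f, theta_s = logic_objective(model, [1, 0, 0, 0], data, alpha=1.0)
        assert theta_s == 0.5

    def test_empty_selection_on_zero_data_scores_zero(self):
        model = chain_model()
        data = LogicData(conditions=[{"stimuli": {"A": 0}}],
                         measurements={(0, "C", 0.0): 0.0})
        theta, theta_f, theta_s = logic_objective(model, [0, 0], data, alpha=1.0)
        assert theta == 0.0 and theta_f == 0.0 and theta_s == 0.0

    def test_no_data_is_an_error(self):
        model = chain_model()
        data = LogicData(conditions=[], measurements={})
        with pytest.raises(ValueError):
            logic_objective(model, [0, 0], data, alpha=0.0)

    def test_components_bounded_and_monotone_in_alpha(self):
        model, data, _alpha, _sel = make_logic_fixture(1)
        rng = np.random.default_rng(2)
        for _ in range(10):
            sel = rng.integers(0, 2, size=model.r)
            t0, f0, s0 = logic_objective(model, sel, data, 0.0)
            t1, f1, s1 = logic_objective(model, sel, data, 0.5)
            assert 0.0 <= f0 <= 1.0 and 0.0 <= s0 <= 1.0
            assert t1 >= t0 and f1 == f0 and s1 == s0

    def test_adding_a_selected_hyperedge_never_lowers_complexity_term(self):
        model, data, _alpha, sel = make_logic_fixture(0)
        _t, _f, s_base = logic_objective(model, sel, data, 1.0)
        grown = sel.copy()
        grown[int(np.argmin(sel))] = 1
        _t2, _f2, s_grown = logic_objective(model, grown, data, 1.0)
        assert s_grown >= s_base


class TestTrainingRecovery:
    def test_vns_recovers_generating_selection(self):
        model, data, alpha, generating = make_logic_fixture(0)
        best_theta, best_sel = enumerate_logic_selections(model, data, alpha)
        np.testing.assert_array_equal(best_sel, generating)
        result = vns_solve(
            make_logic_ip_problem(model, data, alpha),
            VNSOptions(max_evaluations=3000, seed=1),
        )
        assert result.best.penalized == pytest.approx(best_theta)
        np.testing.assert_array_equal(result.best.x.astype(int), generating)

    def test_alpha_zero_matches_enumerated_fit_minimum(self):
        model, data, _alpha, _gen = make_logic_fixture(0)
        best_theta, _sel = enumerate_logic_selections(model, data, 0.0)
        result = vns_solve(
            make_logic_ip_problem(model, data, 0.0),
            VNSOptions(max_evaluations=3000, seed=2),
        )
        assert result.best.penalized == pytest.approx(best_theta)

    def test_huge_alpha_on_zero_data_selects_nothing(self):
        model = chain_model()
        data = LogicData(conditions=[{"stimuli": {"A": 0}}],
                         measurements={(0, "C", 0.0): 0.0})
        result = vns_solve(
            make_logic_ip_problem(model, data, alpha=5.0),
            VNSOptions(max_evaluations=200, seed=0),
        )
        np.testing.assert_array_equal(result.best.x, [0.0, 0.0])
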