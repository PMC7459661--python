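"""Engine unit and property tests: tables, smoothing, Euler, loops."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burnoutsim.engine import (
    Edge,
    ModelGraph,
    ParameterError,
    RunConfig,
    StructuralError,
    TableFunction,
    ValidationError,
    check_edge_signs,
    enumerate_feedback_loops,
    euler_step,
    first_order_smooth_step,
    goal_seek_step,
    run_simulation,
    table_lookup,
)


# --------------------------------------------------------------------------
# Table functions
# --------------------------------------------------------------------------


@pytest.mark.parametrize("tf_points, x, expected", [
    # linear identity
    (((0, 0), (1, 1)), 0.5, 0.5),
    # clamping above the last breakpoint
    (((0, 0), (1, 1)), 1.7, 1.0),
    (((0, 0), (1, 1)), -0.3, 0.0),
    # hand interpolation between the two bracketing points
    (((0, 0), (0.5, 0.9), (1, 1)), 0.25, 0.45),
])
def test_table_lookup_interpolates_and_clamps(tf_points, x, expected):
    tf = TableFunction([p[0] for p in tf_points], [p[1] for p in tf_points])
    assert table_lookup(tf, x) == pytest.approx(expected)


@pytest.mark.parametrize("xs, ys", [
    ((1, 0), (0, 1)),          # descending
    ((0, 0, 1), (0, 1, 1)),    # repeated breakpoint
    ((0,), (1,)),              # too short
    ((0, 1), (1,)),            # length mismatch
])
def test_malformed_table_rejected(xs, ys):
    with pytest.raises(ValidationError):
        TableFunction(xs, ys)


# --------------------------------------------------------------------------
# Smoothing and goal seeking
# --------------------------------------------------------------------------


def test_smoothing_fixed_point():
    for tau, dt in [(1.0, 0.1), (8.0, 2.0), (100.0, 1.0)]:
        assert first_order_smooth_step(0.7, 0.7, tau, dt) == 0.7


def test_smoothing_reaches_target_in_one_step_when_dt_equals_tau():
    with pytest.warns(UserWarning):
        assert first_order_smooth_step(0.0, 1.0, 4.0, 4.0) == pytest.approx(1.0)


def test_smoothing_matches_exponential_closed_form():
    # x(t) = target + (x0 - target) exp(-t/tau), checked after one tau
    tau, dt = 8.0, 0.01
    x = 0.0
    for _ in range(int(tau / dt)):
        x = first_order_smooth_step(x, 1.0, tau, dt)
    assert x == pytest.approx(1 - math.exp(-1), abs=1e-3)


def test_goal_seek_matches_exponential_closed_form():
    adjust, dt = 10.0, 0.01
    x = 0.0
    for _ in range(int(adjust / dt)):
        x = goal_seek_step(x, 1.0, adjust, dt)
    assert x == pytest.approx(1 - math.exp(-1), abs=1e-3)


def test_goal_seek_lags_ramp_by_adjustment_time():
    # chasing target(t) = r*t, the steady-state lag is r * adjust_time
    adjust, dt, rate = 5.0, 0.01, 0.02
    x, t = 0.0, 0.0
    for _ in range(int(200 / dt)):
        x = goal_seek_step(x, rate * t, adjust, dt)
        t += dt
    assert (rate * t - x) == pytest.approx(rate * adjust, rel=1e-2)


@pytest.mark.parametrize("func", [first_order_smooth_step, goal_seek_step])
def test_nonpositive_time_constant_rejected(func):
    with pytest.raises(ParameterError):
        func(0.0, 1.0, 0.0, 0.1)
    with pytest.raises(ParameterError):
        func(0.0, 1.0, -3.0, 0.1)


@given(
    x0=st.floats(0, 1), target=st.floats(0, 1),
    tau=st.floats(0.5, 50), dt=st.floats(0.001, 0.1),
)
@settings(max_examples=100, deadline=None)
def test_smoothing_moves_toward_target_without_overshoot(x0, target, tau, dt):
    new = first_order_smooth_step(x0, target, tau, min(dt, tau))
    assert min(x0, target) - 1e-12 <= new <= max(x0, target) + 1e-12


# --------------------------------------------------------------------------
# Euler stepping and simulation
# --------------------------------------------------------------------------


def _one_stock_model(inflow_expr="0.1", outflow_expr="0.0"):
    return ModelGraph(
        variables={"s": "stock", "inflow": "flow", "outflow": "flow"},
        equations={"inflow": inflow_expr, "outflow": outflow_expr},
        net_flow={"s": (("inflow",), ("outflow",))},
    )


def test_linear_accumulation():
    model = _one_stock_model("0.1", "0.0")
    state = {"s": 0.0}
    for _ in range(10):
        state = euler_step(model, state, 1.0)
    assert state["s"] == pytest.approx(1.0)


def test_conservation_when_inflow_equals_outflow():
    model = _one_stock_model("0.25", "0.25")
    state = {"s": 0.4}
    for _ in range(50):
        state = euler_step(model, state, 0.5)
    assert state["s"] == 0.4


def test_hand_euler_arithmetic_stock_integral():
    # stock' = recovery - load: 0.5 + 4 steps * 0.5 wk * (0.2 - 0.05) = 0.8
    model = ModelGraph(
        variables={"capacity": "stock", "recovery": "flow", "load": "flow",
                   "recovery_rate": "constant", "load_rate": "constant"},
        equations={"recovery": "recovery_rate", "load": "load_rate"},
        net_flow={"capacity": (("recovery",), ("load",))},
    )
    state = {"capacity": 0.5, "recovery_rate": 0.2, "load_rate": 0.05}
    for _ in range(4):
        state = euler_step(model, state, 0.5)
    assert state["capacity"] == pytest.approx(0.8)


def test_cyclic_auxiliary_dependency_names_the_cycle():
    with pytest.raises(StructuralError, match="a.*b|b.*a"):
        ModelGraph(
            variables={"a": "auxiliary", "b": "auxiliary"},
            equations={"a": "b + 1", "b": "a + 1"},
        )


def test_missing_state_variable_is_named():
    model = _one_stock_model()
    with pytest.raises(ValidationError, match="s"):
        euler_step(model, {}, 1.0)


def test_zero_flow_simulation_is_constant():
    model = _one_stock_model("0.0", "0.0")
    traj = run_simulation(model, RunConfig(horizon=10, dt=0.5), {"s": 0.3})
    assert np.all(traj["s"] == 0.3)
    assert len(traj.times) == 21


def test_run_simulation_is_deterministic():
    model = _one_stock_model("0.1 * (1 - s)", "0.02 * s")
    config = RunConfig(horizon=20, dt=0.25)
    a = run_simulation(model, config, {"s": 0.1})
    b = run_simulation(model, config, {"s": 0.1})
    assert a.times.tobytes() == b.times.tobytes()
    for name in a.variables:
        assert a[name].tobytes() == b[name].tobytes()


def test_euler_endpoint_error_is_first_order_in_dt():
    # error vs a dt/10 reference scales ~linearly: slope 1 on log-log
    model = _one_stock_model("0.3 * (1 - s)", "0.1 * s")
    horizon = 8.0

    def endpoint(dt):
        traj = run_simulation(model, RunConfig(horizon=horizon, dt=dt), {"s": 0.0})
        return traj["s"][-1]

    reference = endpoint(0.025)
    errors = [abs(endpoint(dt) - reference) for dt in (1.0, 0.5, 0.25)]
    slopes = [
        math.log2(errors[i] / errors[i + 1]) for i in range(2)
    ]
    for slope in slopes:
        assert slope == pytest.approx(1.0, abs=0.1)


def test_run_config_validation():
    with pytest.raises(ParameterError):
        RunConfig(horizon=10, dt=0.0)
    with pytest.raises(ParameterError):
        RunConfig(horizon=10, dt=3.0)  # not an integer number of steps
    with pytest.raises(ParameterError):
        RunConfig(horizon=-1, dt=0.5)


def test_model_graph_json_round_trip():
    model = ModelGraph(
        variables={"s": "stock", "f": "flow", "a": "auxiliary", "k": "constant"},
        equations={"f": "k * a", "a": "curve(s)"},
        net_flow={"s": (("f",), ())},
        edges=(Edge("s", "a", "+"), Edge("a", "f", "+"), Edge("f", "s", "+", True)),
        tables={"curve": TableFunction((0, 1), (0, 1))},
        bounded=frozenset({"s"}),
    )
    restored = ModelGraph.from_json(model.to_json())
    assert restored.to_dict() == model.to_dict()
    state = {"s": 0.5, "k": 2.0}
    assert euler_step(restored, state, 0.1) == euler_step(model, state, 0.1)


# --------------------------------------------------------------------------
# Feedback-loop enumeration
# --------------------------------------------------------------------------


def _two_node_model(sign_ab, sign_ba):
    return ModelGraph(
        variables={"a": "constant", "b": "constant"},
        edges=(Edge("a", "b", sign_ab), Edge("b", "a", sign_ba)),
    )


def test_two_node_reinforcing_loop():
    loops = enumerate_feedback_loops(_two_node_model("+", "+"))
    assert len(loops) == 1
    assert loops[0].polarity == "reinforcing"
    assert loops[0].cycle == ("a", "b")


def test_two_node_balancing_loop():
    loops = enumerate_feedback_loops(_two_node_model("+", "-"))
    assert [lp.polarity for lp in loops] == ["balancing"]


def test_acyclic_graph_has_no_loops():
    model = ModelGraph(
        variables={"a": "constant", "b": "constant", "c": "constant"},
        edges=(Edge("a", "b", "+"), Edge("b", "c", "-")),
    )
    assert enumerate_feedback_loops(model) == []


def _brute_force_cycles(nodes, edges):
    """Independent DFS enumeration of simple cycles with polarities."""
    adjacency = {n: [] for n in nodes}
    sign = {}
    for src, dst, s in edges:
        adjacency[src].append(dst)
        sign[(src, dst)] = s
    found = set()

    def walk(start, current, path):
        for nxt in adjacency[current]:
            if nxt == start and len(path) >= 1:
                cycle = tuple(path)
                k = min(range(len(cycle)), key=lambda i: cycle[i])
                canon = cycle[k:] + cycle[:k]
                product = 1
                for x, y in zip(canon, canon[1:] + canon[:1]):
                    product *= 1 if sign[(x, y)] == "+" else -1
                found.add((canon, "reinforcing" if product > 0 else "balancing"))
            elif nxt not in path and nxt > start:
                walk(start, nxt, path + [nxt])

    for n in sorted(nodes):
        walk(n, n, [n])
    return found


@pytest.mark.parametrize("seed", range(40))
def test_loop_enumeration_matches_brute_force_on_random_digraphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    nodes = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.4:
                edges.append((nodes[i], nodes[j], "+" if rng.random() < 0.5 else "-"))
    model = ModelGraph(
        variables={n_: "constant" for n_ in nodes},
        edges=tuple(Edge(s, t, sg) for s, t, sg in edges),
    )
    ours = {(lp.cycle, lp.polarity) for lp in enumerate_feedback_loops(model)}
    assert ours == _brute_force_cycles(nodes, edges)


def test_max_len_bounds_cycle_length():
    nodes = ["a", "b", "c", "d"]
    edges = tuple(
        Edge(nodes[i], nodes[(i + 1) % 4], "+") for i in range(4)
    ) + (Edge("b", "a", "+"),)
    model = ModelGraph(variables={n: "constant" for n in nodes}, edges=edges)
    assert {lp.length for lp in enumerate_feedback_loops(model)} == {2, 4}
    assert {lp.length for lp in enumerate_feedback_loops(model, max_len=2)} == {2}


# --------------------------------------------------------------------------
# Edge-sign consistency
# --------------------------------------------------------------------------


def test_edge_sign_check_flags_contradiction():
    model = ModelGraph(
        variables={"x": "constant", "y": "auxiliary"},
        equations={"y": "-2 * x"},
        edges=(Edge("x", "y", "+"),),   # wrong: derivative is negative
    )
    with pytest.raises(StructuralError, match="x -> y"):
        check_edge_signs(model, {"x": 0.5})


def test_edge_sign_check_accepts_weak_zero_derivative():
    model = ModelGraph(
        variables={"x": "constant", "z": "constant", "y": "auxiliary"},
        equations={"y": "min(x, z)"},
        edges=(Edge("x", "y", "+"), Edge("z", "y", "+")),
    )
    measured = check_edge_signs(model, {"x": 0.2, "z": 0.8})
    assert measured[Edge("x", "y", "+")] == pytest.approx(1.0)
    assert measured[Edge("z", "y", "+")] == pytest.approx(0.0)
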