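"""Full burnout model: structure, named loops, update rules, switches."""

import numpy as np
import pytest
from dataclasses import replace

from burnoutsim.burnout import (
    BURNOUT_AUXILIARIES,
    BURNOUT_STOCKS,
    BurnoutParams,
    DEFAULT_CAPACITY_CURVE,
    DEFAULT_MOTIVATION_CURVE,
    NAMED_LOOPS,
    build_burnout_model,
    composite_step,
    compute_auxiliaries,
    demand_update,
    effort_update,
    initial_burnout_state,
    learning_step,
    performance_and_gap,
    stress_and_body_step,
    verify_named_loops,
)
from burnoutsim.engine import (
    Edge,
    ModelGraph,
    RunConfig,
    StructuralError,
    ValidationError,
    check_edge_signs,
    euler_step,
    run_simulation,
)
from burnoutsim.scenarios import persona_params


@pytest.fixture(scope="module")
def default_model():
    params = BurnoutParams()
    return params, build_burnout_model(params)


# --------------------------------------------------------------------------
# Structure
# --------------------------------------------------------------------------


def test_all_declared_state_variables_present(default_model):
    _, model = default_model
    for name in BURNOUT_STOCKS:
        assert model.variables.get(name) == "stock", name
    for name in BURNOUT_AUXILIARIES:
        assert model.variables.get(name) == "auxiliary", name


def test_all_five_named_loops_found_with_expected_polarities(default_model):
    _, model = default_model
    found = verify_named_loops(model)
    assert set(found) == set(NAMED_LOOPS)
    for name, (_, expected_polarity) in NAMED_LOOPS.items():
        assert found[name].polarity == expected_polarity, name


def test_removing_learning_edges_reports_exactly_that_loop_missing(default_model):
    params, model = default_model
    pruned = ModelGraph(
        variables=dict(model.variables),
        equations=dict(model.equations),
        net_flow=dict(model.net_flow),
        edges=tuple(
            e for e in model.edges
            if not (e.source == "symptoms_of_exhaustion"
                    and e.target in ("work_goal_relevance", "expected_consequences"))
        ),
        tables=dict(model.tables),
        bounded=model.bounded,
    )
    with pytest.raises(StructuralError) as excinfo:
        verify_named_loops(pruned)
    message = str(excinfo.value)
    assert "learning to adjust goals and perception" in message
    for other in set(NAMED_LOOPS) - {"learning to adjust goals and perception"}:
        assert other not in message


@pytest.mark.parametrize("pid", ["P1", "P2", "P3"])
def test_edge_signs_consistent_at_initial_state(pid):
    params = persona_params(pid).params()
    model = build_burnout_model(params)
    check_edge_signs(model, initial_burnout_state(params))


def test_graph_step_equals_composition_of_update_rules(default_model):
    params, model = default_model
    state = initial_burnout_state(params)
    dt = 0.125
    for _ in range(400):
        via_graph = euler_step(model, state, dt)
        via_rules = composite_step(state, params, dt)
        for stock in model.stocks:
            assert via_graph[stock] == via_rules[stock]
        state = via_graph


# --------------------------------------------------------------------------
# Elementary update rules
# --------------------------------------------------------------------------


def test_zero_task_load_gives_zero_indicated_demand():
    params = BurnoutParams()
    # demands decay toward the performance-extrapolated floor only
    new = demand_update(0.0, 0.9, 0.5, 0.4, 0.0, params, 0.125)
    assert new < 0.4


def test_demands_nondecreasing_in_hindrances():
    params = BurnoutParams()
    results = [
        demand_update(0.8, 0.8, h, 0.3, 0.2, params, 0.125)
        for h in np.linspace(0, 1, 11)
    ]
    assert all(b >= a - 1e-15 for a, b in zip(results, results[1:]))


def test_demand_stock_converges_to_constant_indicated_demand():
    # closed form: exponential approach with the adjustment time constant
    params = BurnoutParams(effect_of_performance_on_demands=1e-9)
    task_load, requirements, hindrances = 0.8, 0.75, 0.0
    indicated = task_load * requirements
    demands = 0.1
    dt = 0.01
    for _ in range(int(10 * params.time_to_adjust_demands / dt)):
        demands = demand_update(task_load, requirements, hindrances,
                                demands, 0.0, params, dt)
    assert demands == pytest.approx(indicated, abs=1e-4)


def test_demand_update_rejects_out_of_range_inputs():
    with pytest.raises(ValidationError):
        demand_update(1.4, 0.5, 0.2, 0.3, 0.3, BurnoutParams(), 0.125)


@pytest.mark.parametrize("motivation, expected", [
    (1.0, "demands"),   # fully motivated, ample capacity: effort = demands
    (0.0, "zero"),      # no motivation: no effort
])
def test_effort_update_limits(motivation, expected):
    effort = effort_update(0.6, motivation, 1.0, DEFAULT_CAPACITY_CURVE,
                           DEFAULT_MOTIVATION_CURVE)
    if expected == "demands":
        assert effort == pytest.approx(0.6)
    else:
        assert effort == 0.0


def test_effort_nondecreasing_in_perceived_capacity():
    efforts = [
        effort_update(0.9, 0.9, c, DEFAULT_CAPACITY_CURVE, DEFAULT_MOTIVATION_CURVE)
        for c in np.linspace(0, 1, 101)
    ]
    assert all(b >= a - 1e-15 for a, b in zip(efforts, efforts[1:]))


def test_performance_and_gap_arithmetic():
    assert performance_and_gap(0.5, 1.0, 0.5) == (0.5, 0.0)
    performance, gap = performance_and_gap(0.7, 0.0, 0.6)
    assert performance == 0.0 and gap == 0.6
    rng = np.random.default_rng(7)
    for _ in range(50):
        e, c, d = rng.random(3)
        performance, gap = performance_and_gap(e, c, d)
        assert performance == e * c
        assert gap == max(0.0, d - e * c)


def test_stress_decreases_without_effort_or_gap():
    params = BurnoutParams()
    state = initial_burnout_state(params)
    state.update({"demands": 0.0, "stress": 0.6, "work_goal_relevance": 0.0,
                  "expected_consequences": 0.0, "perceived_gap": 0.0})
    for _ in range(200):
        new = stress_and_body_step(state, params, 0.125)
        if state["stress"] > 0:
            assert new["stress"] < state["stress"]
        state.update(new)


def test_sustained_stress_above_threshold_erodes_cognition():
    params = BurnoutParams()
    state = initial_burnout_state(params)
    state["stress"] = min(1.0, params.exhaustion_onset + 0.3)
    cognition0 = state["cognitive_and_emotional_functions"]
    # pin stress above threshold for many weeks
    for _ in range(400):
        new = stress_and_body_step(state, params, 0.125)
        new["stress"] = state["stress"]
        state.update(new)
    assert state["cognitive_and_emotional_functions"] < cognition0


def test_single_body_step_matches_hand_arithmetic():
    params = BurnoutParams()
    state = initial_burnout_state(params)
    aux = compute_auxiliaries(state, params)
    dt = 0.125
    new = stress_and_body_step(state, params, dt)
    stress_in = (params.stress_gain_effort * aux["mental_effort"]
                 + params.stress_gain_gap * aux["gap_in_performance"]
                 * (1 - state["forced_rest"])) * (1 - state["stress"])
    stress_out = state["stress"] * aux["recovery"] / params.stress_decay_time
    assert new["stress"] == pytest.approx(
        state["stress"] + dt * (stress_in - stress_out), abs=1e-15
    )
    symptom_change = ((1 - state["capacity_for_effort"])
                      - state["symptoms_of_exhaustion"]) / params.symptom_time
    assert new["symptoms_of_exhaustion"] == pytest.approx(
        state["symptoms_of_exhaustion"] + dt * symptom_change, abs=1e-15
    )


class TestLearningStep:
    def _state_with(self, params, **overrides):
        state = initial_burnout_state(params)
        state.update(overrides)
        return state

    def test_all_switches_off_freezes_goal_variables(self):
        params = persona_params("P2").params()
        state = self._state_with(params, symptoms_of_exhaustion=0.9,
                                 burnout_memory=1.0, capacity_for_effort=0.9)
        new = learning_step(state, params, 0.125)
        assert new["work_goal_relevance"] == state["work_goal_relevance"]
        assert new["expected_consequences"] == state["expected_consequences"]

    def test_learning_decreases_both_when_triggered_and_declining(self):
        params = persona_params("P1").params()
        # symptoms above (1 - capacity): the symptom stock is declining
        state = self._state_with(params, symptoms_of_exhaustion=0.8,
                                 burnout_memory=1.0, capacity_for_effort=0.9)
        new = learning_step(state, params, 0.125)
        assert new["work_goal_relevance"] < state["work_goal_relevance"]
        assert new["expected_consequences"] < state["expected_consequences"]

    def test_no_adjustment_before_trigger_crossed(self):
        params = persona_params("P1").params()
        state = self._state_with(params, symptoms_of_exhaustion=0.2,
                                 burnout_memory=0.0, capacity_for_effort=0.9)
        new = learning_step(state, params, 0.125)
        assert new["work_goal_relevance"] == state["work_goal_relevance"]
        assert new["expected_consequences"] == state["expected_consequences"]

    def test_memory_latches_when_symptoms_cross_trigger(self):
        params = persona_params("P1").params()
        state = self._state_with(
            params, symptoms_of_exhaustion=params.learning_trigger + 0.1
        )
        new = learning_step(state, params, 0.5)
        assert new["burnout_memory"] > 0.0


def test_params_validation():
    with pytest.raises(ValidationError):
        BurnoutParams(switch_learning=2)
    with pytest.raises(ValidationError):
        BurnoutParams(work_goal_relevance0=1.2)
    from burnoutsim.engine import ParameterError

    with pytest.raises(ParameterError):
        BurnoutParams(learning_time=0.0)


def test_initial_values_clamped_to_caps():
    params = persona_params("P3").params()
    assert params.expected_consequences0 == 0.6  # printed value preserved
    assert params.effective_expected_consequences0 == 0.5  # cap applied
    assert params.effective_work_goal_relevance0 == 0.6


def test_raising_hindrance_level_never_lowers_peak_stress():
    base = persona_params("P1").params()
    previous = -np.inf
    for level in (0.0, 0.25, 0.5, 0.75, 1.0):
        params = replace(base, hindrance_level=level)
        traj = run_simulation(build_burnout_model(params),
                              RunConfig(horizon=100, dt=0.125),
                              initial_burnout_state(params))
        peak = traj["stress_activation"].max()
        assert peak >= previous - 1e-12
        previous = peak
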