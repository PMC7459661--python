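"""Full system-dynamics model of burnout development and recovery.

The model couples four processes:

1. **Regulating demands** -- the ``demands`` stock goal-seeks toward the
   larger of an *indicated demand* (task load x requirements per task,
   amplified by hindrances) and a performance-extrapolated target: good
   performance raises expectations.  A perceived performance gap exerts
   downward pressure on task load (handing over work) and on requirements
   (lowering one's own bar) -- but each coping route is blocked in
   proportion to how much the person has at stake: high expected
   consequences block handing work over, high work-goal relevance blocks
   lowering the bar.
2. **Regulating effort** -- mental effort is the demand level gated by a
   motivational willingness curve and capped by what the (perceived)
   capacity for effort allows, ``min(demands * g(drive), f(perceived
   capacity))``.  The *drive* is motivation amplified by the perceived
   gap: motivated people push harder when they fall short, and motivation
   also inflates the perception of remaining capacity (concealment).
3. **Impacts on body and mind** -- effort and an unresolved gap feed a
   stress stock; recovery (crowded out by effort) drains it.  Sustained
   effort and stress drain the capacity for effort; stress above an
   exhaustion-onset threshold erodes cognitive and emotional functions,
   which recover only slowly once stress subsides.
4. **Burnout symptoms and learning** -- symptoms of exhaustion track
   depleted capacity with a perception delay.  Once symptoms have crossed
   a trigger level, and while they are declining (the recovery phase),
   a person who *learns* lowers the relevance of work goals and their
   expected consequences toward sustainable levels -- each only if its
   persona switch allows it.

Five named feedback loops thread these processes:

* ``regulating demands`` (balancing) -- a gap leads to shedding task load,
  lowering demands;
* ``pressure to do more`` (reinforcing) -- demands -> effort ->
  performance -> higher demands;
* ``blinded by motivation`` (reinforcing) -- the perceived gap raises
  drive and effort, stress erodes cognition, performance falls, the gap
  widens;
* ``limits of the body`` (balancing) -- effort drains capacity, which
  caps further effort;
* ``learning to adjust goals and perception`` (balancing) -- symptoms of
  exhaustion lower goal relevance and expected consequences, reducing
  motivation, effort and further depletion.

All behavioral variables are dimensionless on [0, 1] (low/mid/high =
0/0.5/1).  Functional forms are the simplest members of their class
consistent with the declared edge polarities and the qualitative persona
trajectories; each is isolated behind a named function so alternatives can
be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .engine import (
    Edge,
    FeedbackLoop,
    ModelGraph,
    ParameterError,
    StructuralError,
    TableFunction,
    ValidationError,
    enumerate_feedback_loops,
    goal_seek_step,
    table_lookup,
)

__all__ = [
    "BurnoutParams",
    "DEFAULT_MOTIVATION_CURVE",
    "DEFAULT_CAPACITY_CURVE",
    "BURNOUT_STOCKS",
    "BURNOUT_AUXILIARIES",
    "NAMED_LOOPS",
    "PROCESS_MAP",
    "build_burnout_model",
    "initial_burnout_state",
    "compute_auxiliaries",
    "demand_update",
    "effort_update",
    "performance_and_gap",
    "stress_and_body_step",
    "learning_step",
    "verify_named_loops",
]

#: Willingness-to-invest-effort as a function of drive: zero without any
#: motivation, saturating toward one; steepest in the mid range, where small
#: differences in what a person has at stake translate into very different
#: effort regimes.
DEFAULT_MOTIVATION_CURVE = TableFunction(
    xs=(0.0, 0.3, 0.5, 0.7, 1.0),
    ys=(0.0, 0.4, 0.85, 0.95, 1.0),
)

#: Available effort as a function of (perceived) capacity for effort:
#: nearly flat close to full capacity, with a cliff once the reserve is
#: depleted -- the sharp decline in the ability to invest effort.
DEFAULT_CAPACITY_CURVE = TableFunction(
    xs=(0.0, 0.35, 0.55, 0.75, 1.0),
    ys=(0.0, 0.03, 0.45, 0.85, 1.0),
)


@dataclass(frozen=True)
class BurnoutParams:
    """Parameterization of the full burnout model.

    The first seven fields are the persona-level controls (policy values,
    initial states and switches); the rest are shared structural
    parameters, calibrated once against the qualitative persona
    trajectories and then frozen.  Time constants are in weeks; every
    behavioral quantity is dimensionless on [0, 1].
    """

    # persona-level (the seven scenario-table columns)
    maximum_expected_consequences: float = 1.0
    maximum_work_goal_relevance: float = 1.0
    work_goal_relevance0: float = 0.6
    expected_consequences0: float = 0.6
    switch_allow_expected_consequences_to_change: int = 1
    switch_allow_work_goal_relevance_to_change: int = 1
    switch_learning: int = 1

    # demand composition and adjustment
    base_task_load: float = 0.9
    base_requirements: float = 0.9
    hindrance_level: float = 0.2
    hindrance_gain: float = 0.5
    route_baseline: float = 0.5
    route2_gain: float = 0.5
    route3_gain: float = 0.5
    effect_of_performance_on_demands: float = 1.8
    time_to_adjust_demands: float = 8.0

    # effort regulation
    drive_gain: float = 3.0
    concealment_gain: float = 0.1
    capacity_perception_time: float = 6.0
    motivation_curve: TableFunction = field(default=DEFAULT_MOTIVATION_CURVE)
    effort_capacity_curve: TableFunction = field(default=DEFAULT_CAPACITY_CURVE)
    perceived_gap_time: float = 3.0

    # stress and body
    stress_gain_effort: float = 0.55
    stress_gain_gap: float = 0.25
    stress_decay_time: float = 4.0
    capacity_recovery_time: float = 8.0
    capacity_load_gain: float = 0.07
    capacity_stress_gain: float = 0.08
    cognitive_erosion_gain: float = 0.15
    cognitive_recovery_time: float = 12.0
    exhaustion_onset: float = 0.6
    collapse_threshold: float = 0.45
    reengage_threshold: float = 0.7
    rest_switch_time: float = 1.0
    rest_effort_residual: float = 0.1

    # symptoms, efficacy and learning
    symptom_time: float = 4.0
    efficacy_time: float = 4.0
    learning_trigger: float = 0.45
    memory_time: float = 1.0
    learning_time: float = 4.0
    learned_work_goal_relevance: float = 0.4
    learned_expected_consequences: float = 0.4

    def __post_init__(self):
        for name in (
            "time_to_adjust_demands", "perceived_gap_time", "stress_decay_time",
            "capacity_perception_time",
            "capacity_recovery_time", "cognitive_recovery_time", "symptom_time",
            "efficacy_time", "memory_time", "learning_time",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be a positive number of weeks")
        for name in (
            "maximum_expected_consequences", "maximum_work_goal_relevance",
            "work_goal_relevance0", "expected_consequences0", "hindrance_level",
            "exhaustion_onset", "learning_trigger", "collapse_threshold",
            "reengage_threshold", "rest_effort_residual",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        for name in (
            "switch_allow_expected_consequences_to_change",
            "switch_allow_work_goal_relevance_to_change",
            "switch_learning",
        ):
            if getattr(self, name) not in (0, 1):
                raise ValidationError(f"{name} must be 0 or 1")

    @property
    def effective_work_goal_relevance0(self) -> float:
        """Initial work-goal relevance clamped to its cap."""
        return min(self.work_goal_relevance0, self.maximum_work_goal_relevance)

    @property
    def effective_expected_consequences0(self) -> float:
        """Initial expected consequences clamped to its cap."""
        return min(self.expected_consequences0, self.maximum_expected_consequences)


#: Stocks of the full model (state carried between steps).
BURNOUT_STOCKS = (
    "demands",
    "stress",
    "capacity_for_effort",
    "cognitive_and_emotional_functions",
    "symptoms_of_exhaustion",
    "work_goal_relevance",
    "expected_consequences",
    "perceived_gap",
    "perceived_capacity_for_effort",
    "forced_rest",
    "self_efficacy",
    "burnout_memory",
)

#: Instantaneous variables recomputed every step.
BURNOUT_AUXILIARIES = (
    "task_load",
    "requirements_per_task",
    "hindrances",
    "indicated_demand",
    "motivation_to_meet_demands",
    "drive_to_meet_demands",
    "capacity_signal",
    "mental_effort",
    "performance",
    "gap_in_performance",
    "recovery",
    "stress_activation",
    "demand_target",
    "learning_active",
)

_PARAM_CONSTANTS = (
    "maximum_expected_consequences",
    "maximum_work_goal_relevance",
    "switch_allow_expected_consequences_to_change",
    "switch_allow_work_goal_relevance_to_change",
    "switch_learning",
    "base_task_load",
    "base_requirements",
    "hindrance_level",
    "hindrance_gain",
    "route_baseline",
    "route2_gain",
    "route3_gain",
    "effect_of_performance_on_demands",
    "time_to_adjust_demands",
    "drive_gain",
    "concealment_gain",
    "capacity_perception_time",
    "perceived_gap_time",
    "stress_gain_effort",
    "stress_gain_gap",
    "stress_decay_time",
    "capacity_recovery_time",
    "capacity_load_gain",
    "capacity_stress_gain",
    "cognitive_erosion_gain",
    "cognitive_recovery_time",
    "exhaustion_onset",
    "collapse_threshold",
    "reengage_threshold",
    "rest_switch_time",
    "rest_effort_residual",
    "symptom_time",
    "efficacy_time",
    "learning_trigger",
    "memory_time",
    "learning_time",
    "learned_work_goal_relevance",
    "learned_expected_consequences",
)

#: Variable -> process color grouping of the causal diagram.
PROCESS_MAP = {
    "task_load": "regulating demands",
    "requirements_per_task": "regulating demands",
    "hindrances": "regulating demands",
    "indicated_demand": "regulating demands",
    "demand_target": "regulating demands",
    "demands": "regulating demands",
    "mental_effort": "regulating effort",
    "motivation_to_meet_demands": "regulating effort",
    "drive_to_meet_demands": "regulating effort",
    "perceived_capacity_for_effort": "regulating effort",
    "capacity_signal": "regulating effort",
    "performance": "regulating effort",
    "gap_in_performance": "regulating effort",
    "perceived_gap": "regulating effort",
    "self_efficacy": "regulating effort",
    "stress": "impacts on body and mind",
    "stress_activation": "impacts on body and mind",
    "recovery": "impacts on body and mind",
    "capacity_for_effort": "impacts on body and mind",
    "forced_rest": "impacts on body and mind",
    "cognitive_and_emotional_functions": "impacts on body and mind",
    "symptoms_of_exhaustion": "burnout symptoms",
    "burnout_memory": "burnout symptoms",
    "work_goal_relevance": "burnout symptoms",
    "expected_consequences": "burnout symptoms",
    "learning_active": "burnout symptoms",
}


# --------------------------------------------------------------------------
# Elementary update rules (the functional forms, kept swappable)
# --------------------------------------------------------------------------


def _check_unit_interval(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {value}")


def demand_update(task_load: float, requirements_per_task: float,
                  hindrances: float, demands_stock: float, performance: float,
                  params: BurnoutParams, dt: float) -> float:
    """One goal-seeking step of the demands stock.

    The indicated demand combines task load and requirements per task,
    amplified by hindrances; the stock chases the larger of that and the
    performance-extrapolated expectation (the pressure to do more).
    """
    _check_unit_interval(
        task_load=task_load, requirements_per_task=requirements_per_task,
        hindrances=hindrances, demands_stock=demands_stock, performance=performance,
    )
    indicated = min(
        1.0,
        task_load * requirements_per_task * (1.0 + params.hindrance_gain * hindrances),
    )
    extrapolated = min(1.0, performance * params.effect_of_performance_on_demands)
    target = max(indicated, extrapolated)
    new = goal_seek_step(demands_stock, target, params.time_to_adjust_demands, dt)
    return min(1.0, max(0.0, new))


def effort_update(demands: float, motivation_to_meet_demands: float,
                  perceived_capacity_for_effort: float,
                  effort_capacity_curve: TableFunction,
                  motivation_curve: TableFunction = DEFAULT_MOTIVATION_CURVE) -> float:
    """Mental effort: demands gated by willingness, capped by capacity.

    ``min(demands * g(motivation), f(perceived capacity))`` with ``g``
    nondecreasing, ``g(0) = 0`` and ``g(1) = 1``: a person with nothing at
    stake invests nothing, a fully motivated person works at the demand
    level for as long as capacity permits.
    """
    _check_unit_interval(
        demands=demands, motivation_to_meet_demands=motivation_to_meet_demands,
        perceived_capacity_for_effort=perceived_capacity_for_effort,
    )
    willing = demands * table_lookup(motivation_curve, motivation_to_meet_demands)
    able = table_lookup(effort_capacity_curve, perceived_capacity_for_effort)
    return min(willing, able)


def performance_and_gap(mental_effort: float,
                        cognitive_and_emotional_functions: float,
                        demands: float) -> tuple[float, float]:
    """Performance delivered, and the shortfall against the demands.

    Effort converts to performance in proportion to intact cognitive and
    emotional functions; the gap is the unmet part of the demands and is
    never negative.
    """
    _check_unit_interval(
        mental_effort=mental_effort,
        cognitive_and_emotional_functions=cognitive_and_emotional_functions,
        demands=demands,
    )
    performance = mental_effort * cognitive_and_emotional_functions
    gap = max(0.0, demands - performance)
    return performance, gap


def compute_auxiliaries(state: Mapping[str, float],
                        params: BurnoutParams) -> dict[str, float]:
    """Evaluate every instantaneous variable from the current stocks."""
    wgr = state["work_goal_relevance"]
    ec = state["expected_consequences"]
    pgap = state["perceived_gap"]
    motivation = wgr * ec
    drive = min(1.0, motivation * (1.0 + params.drive_gain * motivation * pgap))
    capacity = state["capacity_for_effort"]
    capacity_signal = capacity + params.concealment_gain * drive * (1.0 - capacity)
    perceived_capacity = state["perceived_capacity_for_effort"]
    effort = effort_update(
        state["demands"], drive, perceived_capacity,
        params.effort_capacity_curve, params.motivation_curve,
    ) * (1.0 - (1.0 - params.rest_effort_residual) * state["forced_rest"])
    performance, gap = performance_and_gap(
        effort, state["cognitive_and_emotional_functions"], state["demands"]
    )
    task_load = (
        params.base_task_load
        * (ec + (1.0 - ec) * performance)
        * (1.0 - params.route2_gain * (1.0 - ec) * (params.route_baseline + pgap))
    )
    requirements = params.base_requirements * (
        1.0 - params.route3_gain * (1.0 - wgr) * (params.route_baseline + pgap)
    )
    hindrances = params.hindrance_level
    indicated = min(
        1.0,
        task_load * requirements * (1.0 + params.hindrance_gain * hindrances),
    )
    target = max(
        indicated,
        min(1.0, performance * params.effect_of_performance_on_demands),
    )
    symptom_change = (
        (1.0 - capacity) - state["symptoms_of_exhaustion"]
    ) / params.symptom_time
    learning_active = (
        params.switch_learning * state["burnout_memory"] * (symptom_change < 0)
    )
    return {
        "task_load": task_load,
        "requirements_per_task": requirements,
        "hindrances": hindrances,
        "indicated_demand": indicated,
        "motivation_to_meet_demands": motivation,
        "drive_to_meet_demands": drive,
        "capacity_signal": capacity_signal,
        "mental_effort": effort,
        "performance": performance,
        "gap_in_performance": gap,
        "recovery": 1.0 - effort,
        "stress_activation": state["stress"],
        "demand_target": target,
        "learning_active": float(learning_active),
    }


def stress_and_body_step(state: Mapping[str, float], params: BurnoutParams,
                         dt: float) -> dict[str, float]:
    """Advance stress, capacity, cognition and exhaustion symptoms by dt.

    Stress accumulates with effort and with an unresolved performance gap
    and decays with recovery; capacity for effort drains in proportion to
    effort and stress and refills through recovery (which effort crowds
    out); cognitive and emotional functions erode while stress exceeds the
    exhaustion-onset threshold and regain slowly below it; symptoms of
    exhaustion follow depleted capacity with a perception delay.
    """
    aux = compute_auxiliaries(state, params)
    stress = state["stress"]
    capacity = state["capacity_for_effort"]
    cognition = state["cognitive_and_emotional_functions"]
    symptoms = state["symptoms_of_exhaustion"]

    stress_in = (
        params.stress_gain_effort * aux["mental_effort"]
        + params.stress_gain_gap * aux["gap_in_performance"]
        * (1.0 - state["forced_rest"])
    ) * (1.0 - stress)
    stress_out = stress * aux["recovery"] / params.stress_decay_time
    capacity_in = aux["recovery"] * (1.0 - capacity) / params.capacity_recovery_time
    capacity_out = capacity * (
        params.capacity_load_gain * aux["mental_effort"]
        + params.capacity_stress_gain * stress
    )
    erosion = (
        params.cognitive_erosion_gain
        * max(0.0, stress - params.exhaustion_onset)
        * cognition
    )
    repair = (
        max(0.0, params.exhaustion_onset - stress) / params.exhaustion_onset
        * (1.0 - cognition) / params.cognitive_recovery_time
    )
    symptom_change = ((1.0 - capacity) - symptoms) / params.symptom_time

    out = dict(state)
    out["stress"] = _clamp01(stress + dt * (stress_in - stress_out))
    out["capacity_for_effort"] = _clamp01(capacity + dt * (capacity_in - capacity_out))
    out["cognitive_and_emotional_functions"] = _clamp01(
        cognition + dt * (repair - erosion)
    )
    out["symptoms_of_exhaustion"] = _clamp01(symptoms + dt * symptom_change)
    return out


def learning_step(state: Mapping[str, float], params: BurnoutParams,
                  dt: float) -> dict[str, float]:
    """Advance the learning stocks (goal relevance, expected consequences).

    Learning requires the learning switch, a memory of symptoms having
    crossed the trigger threshold, and symptoms currently declining (the
    recovery phase).  Each variable adjusts toward its learned sustainable
    level only if its own switch allows change; with all switches off the
    values are frozen at their initial levels.
    """
    aux = compute_auxiliaries(state, params)
    out = dict(state)
    trigger_crossed = state["symptoms_of_exhaustion"] > params.learning_trigger
    out["burnout_memory"] = _clamp01(
        state["burnout_memory"]
        + dt * trigger_crossed * (1.0 - state["burnout_memory"]) / params.memory_time
    )
    active = aux["learning_active"]
    wgr_target = min(
        params.learned_work_goal_relevance, params.maximum_work_goal_relevance
    )
    ec_target = min(
        params.learned_expected_consequences, params.maximum_expected_consequences
    )
    out["work_goal_relevance"] = _clamp01(
        state["work_goal_relevance"]
        + dt
        * params.switch_allow_work_goal_relevance_to_change
        * active
        * (wgr_target - state["work_goal_relevance"])
        / params.learning_time
    )
    out["expected_consequences"] = _clamp01(
        state["expected_consequences"]
        + dt
        * params.switch_allow_expected_consequences_to_change
        * active
        * (ec_target - state["expected_consequences"])
        / params.learning_time
    )
    return out


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def composite_step(state: Mapping[str, float], params: BurnoutParams,
                   dt: float) -> dict[str, float]:
    """One full model step composed purely from the elementary update rules.

    All rates are evaluated at the pre-step state (explicit Euler), exactly
    as the declarative graph does; a unit test asserts bitwise agreement
    with :func:`engine.euler_step` on the built graph.
    """
    aux = compute_auxiliaries(state, params)
    out = stress_and_body_step(state, params, dt)
    out.update(
        {k: v for k, v in learning_step(state, params, dt).items()
         if k in ("burnout_memory", "work_goal_relevance", "expected_consequences")}
    )
    out["demands"] = demand_update(
        aux["task_load"], aux["requirements_per_task"], aux["hindrances"],
        state["demands"], aux["performance"], params, dt,
    )
    out["perceived_gap"] = _clamp01(goal_seek_step(
        state["perceived_gap"], aux["gap_in_performance"],
        params.perceived_gap_time, dt,
    ))
    out["perceived_capacity_for_effort"] = _clamp01(goal_seek_step(
        state["perceived_capacity_for_effort"], aux["capacity_signal"],
        params.capacity_perception_time, dt,
    ))
    cap = state["capacity_for_effort"]
    fr = state["forced_rest"]
    engaged = max(
        cap < params.collapse_threshold,
        (fr > 0.5) * (cap < params.reengage_threshold),
    )
    out["forced_rest"] = _clamp01(
        fr + dt * (engaged - fr) / params.rest_switch_time
    )
    out["self_efficacy"] = _clamp01(goal_seek_step(
        state["self_efficacy"], 1.0 - aux["gap_in_performance"],
        params.efficacy_time, dt,
    ))
    return out


# --------------------------------------------------------------------------
# The declarative model graph
# --------------------------------------------------------------------------


def build_burnout_model(params: BurnoutParams) -> ModelGraph:
    """Assemble the full model as a :class:`ModelGraph`.

    The graph equations mirror the elementary update rules above exactly
    (a unit test asserts one-step equivalence), so the declarative model
    and the step functions cannot drift apart silently.
    """
    variables = {name: "stock" for name in BURNOUT_STOCKS}
    variables.update({name: "auxiliary" for name in BURNOUT_AUXILIARIES})
    variables.update({name: "constant" for name in _PARAM_CONSTANTS})
    flows = (
        "demand_adjustment", "stress_inflow", "stress_outflow",
        "perceived_capacity_adjustment", "forced_rest_adjustment",
        "capacity_inflow", "capacity_outflow", "cognitive_erosion",
        "cognitive_repair", "symptom_adjustment", "perceived_gap_adjustment",
        "efficacy_adjustment", "memory_inflow", "wgr_adjustment", "ec_adjustment",
    )
    variables.update({name: "flow" for name in flows})

    equations = {
        "hindrances": "hindrance_level",
        "motivation_to_meet_demands": "work_goal_relevance * expected_consequences",
        "drive_to_meet_demands": (
            "min(1, motivation_to_meet_demands"
            " * (1 + drive_gain * motivation_to_meet_demands * perceived_gap))"
        ),
        "capacity_signal": (
            "capacity_for_effort"
            " + concealment_gain * drive_to_meet_demands * (1 - capacity_for_effort)"
        ),
        "perceived_capacity_adjustment": (
            "(capacity_signal - perceived_capacity_for_effort)"
            " / capacity_perception_time"
        ),
        "forced_rest_adjustment": (
            "(max(capacity_for_effort < collapse_threshold,"
            " (forced_rest > 0.5) * (capacity_for_effort < reengage_threshold))"
            " - forced_rest) / rest_switch_time"
        ),
        "mental_effort": (
            "min(demands * g_motivation(drive_to_meet_demands),"
            " f_capacity(perceived_capacity_for_effort))"
            " * (1 - (1 - rest_effort_residual) * forced_rest)"
        ),
        "performance": "mental_effort * cognitive_and_emotional_functions",
        "gap_in_performance": "max(0, demands - performance)",
        "task_load": (
            "base_task_load"
            " * (expected_consequences + (1 - expected_consequences) * performance)"
            " * (1 - route2_gain * (1 - expected_consequences)"
            " * (route_baseline + perceived_gap))"
        ),
        "requirements_per_task": (
            "base_requirements * (1 - route3_gain * (1 - work_goal_relevance)"
            " * (route_baseline + perceived_gap))"
        ),
        "indicated_demand": (
            "min(1, task_load * requirements_per_task"
            " * (1 + hindrance_gain * hindrances))"
        ),
        "demand_target": (
            "max(indicated_demand,"
            " min(1, performance * effect_of_performance_on_demands))"
        ),
        "recovery": "1 - mental_effort",
        "stress_activation": "stress",
        "learning_active": (
            "switch_learning * burnout_memory * (symptom_adjustment < 0)"
        ),
        "demand_adjustment": "(demand_target - demands) / time_to_adjust_demands",
        "stress_inflow": (
            "(stress_gain_effort * mental_effort"
            " + stress_gain_gap * gap_in_performance * (1 - forced_rest))"
            " * (1 - stress)"
        ),
        "stress_outflow": "stress * recovery / stress_decay_time",
        "capacity_inflow": (
            "recovery * (1 - capacity_for_effort) / capacity_recovery_time"
        ),
        "capacity_outflow": (
            "capacity_for_effort * (capacity_load_gain * mental_effort"
            " + capacity_stress_gain * stress)"
        ),
        "cognitive_erosion": (
            "cognitive_erosion_gain * max(0, stress - exhaustion_onset)"
            " * cognitive_and_emotional_functions"
        ),
        "cognitive_repair": (
            "max(0, exhaustion_onset - stress) / exhaustion_onset"
            " * (1 - cognitive_and_emotional_functions) / cognitive_recovery_time"
        ),
        "symptom_adjustment": (
            "((1 - capacity_for_effort) - symptoms_of_exhaustion) / symptom_time"
        ),
        "perceived_gap_adjustment": (
            "(gap_in_performance - perceived_gap) / perceived_gap_time"
        ),
        "efficacy_adjustment": (
            "((1 - gap_in_performance) - self_efficacy) / efficacy_time"
        ),
        "memory_inflow": (
            "(symptoms_of_exhaustion > learning_trigger)"
            " * (1 - burnout_memory) / memory_time"
        ),
        "wgr_adjustment": (
            "switch_allow_work_goal_relevance_to_change * learning_active"
            " * (min(learned_work_goal_relevance, maximum_work_goal_relevance)"
            " - work_goal_relevance) / learning_time"
        ),
        "ec_adjustment": (
            "switch_allow_expected_consequences_to_change * learning_active"
            " * (min(learned_expected_consequences, maximum_expected_consequences)"
            " - expected_consequences) / learning_time"
        ),
    }

    net_flow = {
        "demands": (("demand_adjustment",), ()),
        "stress": (("stress_inflow",), ("stress_outflow",)),
        "capacity_for_effort": (("capacity_inflow",), ("capacity_outflow",)),
        "cognitive_and_emotional_functions": (
            ("cognitive_repair",), ("cognitive_erosion",)
        ),
        "symptoms_of_exhaustion": (("symptom_adjustment",), ()),
        "work_goal_relevance": (("wgr_adjustment",), ()),
        "expected_consequences": (("ec_adjustment",), ()),
        "perceived_gap": (("perceived_gap_adjustment",), ()),
        "perceived_capacity_for_effort": (("perceived_capacity_adjustment",), ()),
        "forced_rest": (("forced_rest_adjustment",), ()),
        "self_efficacy": (("efficacy_adjustment",), ()),
        "burnout_memory": (("memory_inflow",), ()),
    }

    edges = (
        # regulating demands
        Edge("demands", "gap_in_performance", "+"),
        Edge("gap_in_performance", "perceived_gap", "+", True),
        Edge("perceived_gap", "task_load", "-"),
        Edge("performance", "task_load", "+"),
        Edge("perceived_gap", "requirements_per_task", "-"),
        Edge("expected_consequences", "task_load", "+"),
        Edge("work_goal_relevance", "requirements_per_task", "+"),
        Edge("task_load", "demands", "+", True),
        Edge("requirements_per_task", "demands", "+", True),
        Edge("hindrances", "demands", "+", True),
        Edge("performance", "demands", "+", True),
        # regulating effort
        Edge("demands", "mental_effort", "+"),
        Edge("work_goal_relevance", "motivation_to_meet_demands", "+"),
        Edge("expected_consequences", "motivation_to_meet_demands", "+"),
        Edge("motivation_to_meet_demands", "drive_to_meet_demands", "+"),
        Edge("perceived_gap", "drive_to_meet_demands", "+"),
        Edge("drive_to_meet_demands", "mental_effort", "+"),
        Edge("perceived_capacity_for_effort", "mental_effort", "+"),
        Edge("capacity_for_effort", "perceived_capacity_for_effort", "+", True),
        Edge("drive_to_meet_demands", "perceived_capacity_for_effort", "+", True),
        Edge("mental_effort", "performance", "+"),
        Edge("cognitive_and_emotional_functions", "performance", "+"),
        Edge("performance", "gap_in_performance", "-"),
        Edge("gap_in_performance", "self_efficacy", "-", True),
        # impacts on body and mind
        Edge("mental_effort", "stress", "+"),
        Edge("gap_in_performance", "stress", "+"),
        Edge("recovery", "stress", "-"),
        Edge("mental_effort", "recovery", "-"),
        Edge("recovery", "capacity_for_effort", "+"),
        Edge("mental_effort", "capacity_for_effort", "-"),
        Edge("stress", "capacity_for_effort", "-"),
        Edge("stress", "cognitive_and_emotional_functions", "-", True),
        Edge("capacity_for_effort", "forced_rest", "-", True),
        Edge("forced_rest", "mental_effort", "-"),
        Edge("stress", "stress_activation", "+"),
        # burnout symptoms and learning
        Edge("capacity_for_effort", "symptoms_of_exhaustion", "-", True),
        Edge("symptoms_of_exhaustion", "work_goal_relevance", "-", True),
        Edge("symptoms_of_exhaustion", "expected_consequences", "-", True),
    )

    tables = {
        "g_motivation": params.motivation_curve,
        "f_capacity": params.effort_capacity_curve,
    }

    return ModelGraph(
        variables=variables,
        equations=equations,
        net_flow=net_flow,
        edges=edges,
        tables=tables,
        bounded=frozenset(BURNOUT_STOCKS),
    )


def burnout_constants(params: BurnoutParams) -> dict[str, float]:
    return {name: float(getattr(params, name)) for name in _PARAM_CONSTANTS}


def initial_burnout_state(params: BurnoutParams) -> dict[str, float]:
    """The common starting state of all persona scenarios.

    A normal level of invested effort (moderate demands), well rested
    (full capacity for effort), intact cognitive and emotional functions,
    confident (high self-efficacy), and a healthy level of stress
    activation.  Initial goal relevance and expected consequences come
    from the persona parameters, clamped to their caps.
    """
    state = {
        "demands": 0.3,
        "stress": 0.2,
        "capacity_for_effort": 1.0,
        "cognitive_and_emotional_functions": 1.0,
        "symptoms_of_exhaustion": 0.0,
        "work_goal_relevance": params.effective_work_goal_relevance0,
        "expected_consequences": params.effective_expected_consequences0,
        "perceived_gap": 0.1,
        "perceived_capacity_for_effort": 1.0,
        "forced_rest": 0.0,
        "self_efficacy": 0.9,
        "burnout_memory": 0.0,
    }
    state.update(burnout_constants(params))
    return state


# --------------------------------------------------------------------------
# Named feedback loops
# --------------------------------------------------------------------------

#: Variable-set signatures identifying each named loop among the enumerated
#: cycles (a loop matches when its cycle contains every signature variable;
#: the shortest match is reported), with the reconstructed polarity.
NAMED_LOOPS: dict[str, tuple[frozenset[str], str]] = {
    "regulating demands": (
        frozenset({"demands", "gap_in_performance", "task_load"}),
        "balancing",
    ),
    "pressure to do more": (
        frozenset({"demands", "mental_effort", "performance"}),
        "reinforcing",
    ),
    "blinded by motivation": (
        frozenset({
            "drive_to_meet_demands", "stress",
            "cognitive_and_emotional_functions", "gap_in_performance",
        }),
        "reinforcing",
    ),
    "limits of the body": (
        frozenset({
            "mental_effort", "capacity_for_effort",
            "perceived_capacity_for_effort",
        }),
        "balancing",
    ),
    "learning to adjust goals and perception": (
        frozenset({
            "symptoms_of_exhaustion", "work_goal_relevance",
            "motivation_to_meet_demands",
        }),
        "balancing",
    ),
}


def verify_named_loops(model: ModelGraph,
                       max_len: int = 8) -> dict[str, FeedbackLoop]:
    """Match the five named feedback loops to enumerated cycles.

    Each name is identified by a packaged variable-set signature; the
    shortest enumerated cycle containing every signature variable is
    reported (with its polarity, and the name attached as label).  Raises
    :class:`StructuralError` naming every loop that cannot be found.
    """
    loops = enumerate_feedback_loops(model, max_len=max_len)
    found: dict[str, FeedbackLoop] = {}
    missing: list[str] = []
    for name, (signature, _expected) in NAMED_LOOPS.items():
        matches = [lp for lp in loops if signature <= set(lp.cycle)]
        if not matches:
            missing.append(name)
            continue
        best = min(matches, key=lambda lp: (lp.length, lp.cycle))
        found[name] = FeedbackLoop(cycle=best.cycle, polarity=best.polarity, label=name)
    if missing:
        raise StructuralError(
            "missing named feedback loop(s): " + "; ".join(missing)
        )
    return found
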