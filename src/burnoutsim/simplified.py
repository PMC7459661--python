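"""The simplified capacity-effort-demands illustration model.

Four variables capture the core mechanism by which sustained overwork
erodes the ability to work:

* ``capacity_for_effort`` -- a stock filled by a constant ``recovery``
  inflow and drained by a ``load`` outflow proportional to effort;
* ``effort`` -- the lesser of the perceived demands and what the current
  capacity allows, ``min(demands, f(capacity))``, where ``f`` is a concave
  nondecreasing lookup (well-rested people barely feel a small capacity
  dip; depleted people hit a sharp decline);
* ``performance`` -- proportional to effort;
* ``demands`` -- a goal-seeking stock chasing ``performance * gain``: good
  performance raises expectations.

The structure contains exactly one reinforcing loop
(demands -> effort -> performance -> demands) and one balancing loop
(capacity -> effort -> load -> capacity).  From a well-rested, low-demand
start the reinforcing loop dominates: demands and effort grow until the
load outruns recovery, capacity collapses, effort peaks and crashes, and
the system settles into an equilibrium with a capacity well below its
starting value -- the classic overshoot-and-collapse signature of burnout.

The packaged :func:`reference_run` parameterization is calibrated once so
that effort peaks shortly after week 24 and all three reported series
settle (within a +/-2% band) by about week 52, then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import (
    Edge,
    ModelGraph,
    ParameterError,
    RunConfig,
    TableFunction,
    TrajectorySet,
    ValidationError,
    run_simulation,
)

__all__ = [
    "SimplifiedParams",
    "ReferenceRun",
    "build_simplified_model",
    "reference_run",
    "detect_peak_week",
    "detect_settling_week",
    "DEFAULT_EFFORT_CAPACITY_CURVE",
    "REFERENCE_PARAMS",
    "REFERENCE_INITIAL",
]

#: Concave nondecreasing "available effort as a function of capacity for
#: effort" lookup: flat near full capacity, sharp decline once depleted.
DEFAULT_EFFORT_CAPACITY_CURVE = TableFunction(
    xs=(0.0, 0.25, 0.5, 0.75, 1.0),
    ys=(0.0, 0.45, 0.80, 0.95, 1.0),
)


@dataclass(frozen=True)
class SimplifiedParams:
    """Parameters of the simplified model (all rates per week).

    ``effect_of_performance_on_demands`` > 1 makes expectations outrun
    achievement, which is what arms the reinforcing loop.
    """

    initial_capacity: float = 1.0
    initial_demands: float = 0.1
    recovery_rate: float = 0.1125
    load_coefficient: float = 0.25
    effect_of_performance_on_demands: float = 1.5
    time_to_adjust_demands: float = 6.0
    performance_gain: float = 1.0
    effort_capacity_curve: TableFunction = field(default=DEFAULT_EFFORT_CAPACITY_CURVE)

    def __post_init__(self):
        positive = (
            "recovery_rate",
            "load_coefficient",
            "effect_of_performance_on_demands",
            "time_to_adjust_demands",
            "performance_gain",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.initial_capacity <= 1:
            raise ValidationError("initial_capacity must lie in [0, 1]")
        if not 0 <= self.initial_demands <= 1:
            raise ValidationError("initial_demands must lie in [0, 1]")
        ys = self.effort_capacity_curve.ys
        if any(b < a for a, b in zip(ys, ys[1:])):
            raise ValidationError("effort_capacity_curve must be nondecreasing")


def build_simplified_model(params: SimplifiedParams) -> ModelGraph:
    """Assemble the simplified model as a :class:`ModelGraph`.

    Effort obeys ``min(demands, f(capacity))`` pointwise; demands
    goal-seek toward ``performance * effect_of_performance_on_demands``.
    """
    return ModelGraph(
        variables={
            "capacity_for_effort": "stock",
            "demands": "stock",
            "effort": "auxiliary",
            "performance": "auxiliary",
            "load": "flow",
            "recovery": "flow",
            "demand_adjustment": "flow",
            "recovery_rate": "constant",
            "load_coefficient": "constant",
            "effect_of_performance_on_demands": "constant",
            "time_to_adjust_demands": "constant",
            "performance_gain": "constant",
        },
        equations={
            "effort": "min(demands, f_capacity(capacity_for_effort))",
            "performance": "performance_gain * effort",
            "load": "load_coefficient * effort",
            "recovery": "recovery_rate",
            "demand_adjustment": (
                "(performance * effect_of_performance_on_demands - demands)"
                " / time_to_adjust_demands"
            ),
        },
        net_flow={
            "capacity_for_effort": (("recovery",), ("load",)),
            "demands": (("demand_adjustment",), ()),
        },
        edges=(
            Edge("demands", "effort", "+"),
            Edge("capacity_for_effort", "effort", "+"),
            Edge("effort", "performance", "+"),
            Edge("performance", "demands", "+", True),
            Edge("effort", "load", "+"),
            Edge("load", "capacity_for_effort", "-"),
            Edge("recovery", "capacity_for_effort", "+"),
        ),
        tables={"f_capacity": params.effort_capacity_curve},
        bounded=frozenset({"capacity_for_effort", "demands"}),
    )


def initial_state(params: SimplifiedParams) -> dict[str, float]:
    return {
        "capacity_for_effort": params.initial_capacity,
        "demands": params.initial_demands,
        "recovery_rate": params.recovery_rate,
        "load_coefficient": params.load_coefficient,
        "effect_of_performance_on_demands": params.effect_of_performance_on_demands,
        "time_to_adjust_demands": params.time_to_adjust_demands,
        "performance_gain": params.performance_gain,
    }


@dataclass
class ReferenceRun:
    """The frozen reference parameterization, its grid, and its output."""

    params: SimplifiedParams
    config: RunConfig
    traj: TrajectorySet


#: Frozen reference parameterization (calibrated once, see docs/methods.md).
REFERENCE_PARAMS = SimplifiedParams()

#: Well-rested, low-demand starting state of the reference scenario.
REFERENCE_INITIAL = initial_state(REFERENCE_PARAMS)

#: Series reported by the reference scenario.
REPORTED_SERIES = ("capacity_for_effort", "demands", "effort")


def reference_run(dt: float = 0.125, horizon: float = 100.0) -> ReferenceRun:
    """Run the packaged overshoot-and-collapse reference scenario.

    Deterministic: effort rises with demands, peaks shortly after week 24,
    collapses as capacity is drained, and the system settles by about
    week 52 at a capacity below its starting value.
    """
    params = REFERENCE_PARAMS
    config = RunConfig(horizon=horizon, dt=dt)
    traj = run_simulation(build_simplified_model(params), config, initial_state(params))
    return ReferenceRun(params=params, config=config, traj=traj)


def detect_peak_week(series, times) -> float:
    """Time of the global maximum of ``series`` (first occurrence on ties)."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size == 0:
        raise ValidationError("cannot locate a peak in an empty series")
    if series.shape != times.shape:
        raise ValidationError("series and times must have equal length")
    return float(times[int(np.argmax(series))])


def detect_settling_week(traj: TrajectorySet, band: float = 0.02,
                         variables=None) -> float:
    """Earliest time after which every series stays near its final value.

    A series counts as settled from time ``T`` when, for every later grid
    point, it deviates from its final value by at most ``band`` times its
    own overall range (max - min over the run); the range normalization
    makes the criterion meaningful for series that decay toward zero and
    makes constant series settle immediately.  Returns the last grid time
    (the horizon) if the criterion is never met before the end.
    """
    if band <= 0:
        raise ParameterError(f"band must be positive, got {band}")
    names = list(variables) if variables is not None else list(traj.variables)
    missing = [n for n in names if n not in traj.series]
    if missing:
        raise ValidationError(f"missing series: {', '.join(missing)}")
    ok = np.ones(len(traj.times), dtype=bool)
    for name in names:
        vals = traj.series[name]
        tol = band * float(vals.max() - vals.min())
        ok &= np.abs(vals - vals[-1]) <= tol + 1e-15
    # last index from which everything stays within band
    settled_from = len(ok) - 1
    for i in range(len(ok) - 1, -1, -1):
        if not ok[i]:
            break
        settled_from = i
    else:
        settled_from = 0
    return float(traj.times[settled_from])
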