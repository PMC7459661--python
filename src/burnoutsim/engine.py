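"""Generic stock-and-flow system dynamics engine.

A model is a declarative graph of named variables, each playing one of four
roles:

``stock``
    An accumulating state variable; its value is the time integral of its
    net flow (inflows minus outflows).
``flow``
    A rate of change attached to one or more stocks, computed each step
    from an expression.
``auxiliary``
    An instantaneous variable computed each step from an expression.
``constant``
    A fixed parameter supplied with the initial state.

Expressions are plain arithmetic strings over variable names, the functions
``min``/``max``/``abs``/``exp``, comparisons (which evaluate to 0/1), and
registered piecewise-linear :class:`TableFunction` lookups called by name.
Auxiliaries and flows must form an acyclic dependency graph once stocks and
constants are treated as sources; they are evaluated in topological order
(alphabetical tie-break for reproducibility).

Integration is explicit Euler.  Stocks declared *bounded* are clamped to
[0, 1] after each step, the convention used throughout this package for
dimensionless behavioral quantities (low/mid/high mapped to 0/0.5/1).

On top of the simulator the module provides the two canonical first-order
adjustment primitives of system dynamics (exponential smoothing and
goal-seeking), enumeration of signed feedback loops on the declared causal
edge set, and a numerical consistency check of declared edge polarities.
"""

from __future__ import annotations

import ast
import heapq
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "BurnoutSimError",
    "ValidationError",
    "ParameterError",
    "StructuralError",
    "TableFunction",
    "table_lookup",
    "Edge",
    "ModelGraph",
    "RunConfig",
    "TrajectorySet",
    "FeedbackLoop",
    "first_order_smooth_step",
    "goal_seek_step",
    "euler_step",
    "run_simulation",
    "enumerate_feedback_loops",
    "check_edge_signs",
]


class BurnoutSimError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(BurnoutSimError):
    """Malformed data: bad table breakpoints, out-of-range inputs, ..."""


class ParameterError(BurnoutSimError):
    """Invalid numeric parameter (non-positive time constant, bad band, ...)."""


class StructuralError(BurnoutSimError):
    """Invalid model structure (cyclic auxiliaries, missing loop, ...)."""


# --------------------------------------------------------------------------
# Table functions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TableFunction:
    """Piecewise-linear lookup with clamped extrapolation.

    ``xs`` must be strictly increasing and the same length as ``ys``
    (at least two breakpoints).  Lookups outside ``[xs[0], xs[-1]]``
    return the end values.
    """

    xs: tuple[float, ...]
    ys: tuple[float, ...]

    def __init__(self, xs: Sequence[float], ys: Sequence[float]):
        object.__setattr__(self, "xs", tuple(float(x) for x in xs))
        object.__setattr__(self, "ys", tuple(float(y) for y in ys))
        if len(self.xs) != len(self.ys):
            raise ValidationError("table xs and ys must have equal length")
        if len(self.xs) < 2:
            raise ValidationError("table needs at least two breakpoints")
        if any(b <= a for a, b in zip(self.xs, self.xs[1:])):
            raise ValidationError("table xs must be strictly increasing")

    def __call__(self, x: float) -> float:
        return float(np.interp(x, self.xs, self.ys))


def table_lookup(tf: TableFunction, x: float) -> float:
    """Evaluate ``tf`` at ``x`` (piecewise-linear, clamped outside range)."""
    return tf(x)


# --------------------------------------------------------------------------
# First-order adjustment primitives
# --------------------------------------------------------------------------


def first_order_smooth_step(current: float, target: float, tau: float, dt: float) -> float:
    """One Euler step of first-order exponential smoothing toward ``target``.

    Models the gradual updating of a perception by averaging past
    information: ``current + dt * (target - current) / tau``.  ``tau`` is
    the smoothing time in weeks.  A warning is emitted when ``dt > tau/4``
    because the discrete step then departs visibly from the continuous
    exponential (at ``dt == tau`` the step lands exactly on the target).
    """
    if tau <= 0:
        raise ParameterError(f"smoothing time must be positive, got {tau}")
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    if dt > tau:
        raise ParameterError(f"dt={dt} exceeds smoothing time tau={tau}")
    if dt > tau / 4:
        warnings.warn(
            f"dt={dt} is coarse relative to tau={tau}; "
            "discretization error may be noticeable",
            stacklevel=2,
        )
    return current + dt * (target - current) / tau


def goal_seek_step(stock: float, target: float, adjust_time: float, dt: float) -> float:
    """One Euler step of a goal-seeking stock adjusting toward ``target``.

    Numerically identical to :func:`first_order_smooth_step`, but kept as a
    distinct primitive: goal-seeking stocks chase an *endogenous* target
    (e.g. demands chasing performance times a pressure gain) rather than
    smoothing an exogenous signal.
    """
    if adjust_time <= 0:
        raise ParameterError(f"adjustment time must be positive, got {adjust_time}")
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    return stock + dt * (target - stock) / adjust_time


# --------------------------------------------------------------------------
# Expressions
# --------------------------------------------------------------------------

_ALLOWED_CALLS = {"min", "max", "abs", "exp"}

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.BoolOp,
    ast.Compare,
    ast.IfExp,
    ast.Call,
    ast.Name,
    ast.Load,
    ast.Constant,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.USub,
    ast.UAdd,
    ast.And,
    ast.Or,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Eq,
    ast.NotEq,
)


def _parse_expression(name: str, src: str, known: set[str], tables: set[str]):
    """Compile an equation, returning (code object, referenced variables)."""
    try:
        tree = ast.parse(src, mode="eval")
    except SyntaxError as exc:
        raise ValidationError(f"equation for '{name}' does not parse: {exc}") from exc
    deps: set[str] = set()
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ValidationError(
                f"equation for '{name}' uses disallowed construct "
                f"{type(node).__name__}"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name):
                raise ValidationError(f"equation for '{name}': only named calls allowed")
            fname = node.func.id
            if fname not in _ALLOWED_CALLS and fname not in tables:
                raise ValidationError(
                    f"equation for '{name}' calls unknown function '{fname}'"
                )
        if isinstance(node, ast.Name):
            ident = node.id
            if ident in known:
                deps.add(ident)
            elif ident not in _ALLOWED_CALLS and ident not in tables:
                raise ValidationError(
                    f"equation for '{name}' references unknown name '{ident}'"
                )
    return compile(tree, filename=f"<equation:{name}>", mode="eval"), deps


# --------------------------------------------------------------------------
# Model graph
# --------------------------------------------------------------------------


class Edge(NamedTuple):
    """A signed causal link of the causal loop diagram.

    ``sign`` is "+" or "-"; ``delayed`` marks links that act through an
    explicit smoothing/accumulation stage rather than instantaneously.
    """

    source: str
    target: str
    sign: str
    delayed: bool = False


_ROLES = ("stock", "flow", "auxiliary", "constant")


@dataclass
class ModelGraph:
    """Declarative stock-and-flow model.

    Parameters
    ----------
    variables
        Map of variable name to role (``stock``/``flow``/``auxiliary``/
        ``constant``).
    equations
        Expression strings for every auxiliary and flow.
    net_flow
        Map of stock name to ``(inflow names, outflow names)``.
    edges
        Signed causal links used for loop enumeration and polarity checks.
        The edge set is the causal-loop-diagram projection of the model:
        implicit first-order self-loops of goal-seeking stocks are not
        declared.
    tables
        Named :class:`TableFunction` objects callable from expressions.
    bounded
        Stocks clamped to [0, 1] after every Euler step.
    """

    variables: dict[str, str]
    equations: dict[str, str] = field(default_factory=dict)
    net_flow: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=dict)
    edges: tuple[Edge, ...] = ()
    tables: dict[str, TableFunction] = field(default_factory=dict)
    bounded: frozenset[str] = frozenset()

    def __post_init__(self):
        self.edges = tuple(Edge(*e) for e in self.edges)
        self.bounded = frozenset(self.bounded)
        self.net_flow = {
            s: (tuple(ins), tuple(outs)) for s, (ins, outs) in self.net_flow.items()
        }
        self._validate_structure()
        self._compile()

    # -- validation ---------------------------------------------------------

    def _validate_structure(self) -> None:
        for name, role in self.variables.items():
            if role not in _ROLES:
                raise ValidationError(f"variable '{name}' has unknown role '{role}'")
        names = set(self.variables)
        if set(self.tables) & names:
            clash = sorted(set(self.tables) & names)
            raise ValidationError(f"table names clash with variables: {clash}")
        for name, role in self.variables.items():
            if role in ("auxiliary", "flow") and name not in self.equations:
                raise ValidationError(f"{role} '{name}' has no equation")
            if role in ("stock", "constant") and name in self.equations:
                raise ValidationError(f"{role} '{name}' must not have an equation")
        for stock, (ins, outs) in self.net_flow.items():
            if self.variables.get(stock) != "stock":
                raise ValidationError(f"net_flow declared for non-stock '{stock}'")
            for f in (*ins, *outs):
                if self.variables.get(f) != "flow":
                    raise ValidationError(
                        f"net flow of '{stock}' references '{f}' which is not a flow"
                    )
        for stock, role in self.variables.items():
            if role == "stock" and stock not in self.net_flow:
                raise ValidationError(f"stock '{stock}' has no net_flow entry")
        for e in self.edges:
            if e.source not in names or e.target not in names:
                raise ValidationError(f"edge {e.source}->{e.target} references unknown variable")
            if e.sign not in ("+", "-"):
                raise ValidationError(f"edge {e.source}->{e.target} has bad sign '{e.sign}'")
        for name in self.bounded:
            if self.variables.get(name) != "stock":
                raise ValidationError(f"bounded variable '{name}' is not a stock")

    def _compile(self) -> None:
        known = set(self.variables)
        tabs = set(self.tables)
        self._codes: dict[str, object] = {}
        self._deps: dict[str, set[str]] = {}
        for name, src in self.equations.items():
            code, deps = _parse_expression(name, src, known, tabs)
            self._codes[name] = code
            self._deps[name] = deps
        self._order = self._topological_order()
        self._namespace_base = {
            "min": min,
            "max": max,
            "abs": abs,
            "exp": math.exp,
            **self.tables,
        }

    def _topological_order(self) -> tuple[str, ...]:
        """Evaluation order of auxiliaries/flows, alphabetical tie-break."""
        nodes = sorted(n for n, r in self.variables.items() if r in ("auxiliary", "flow"))
        nodeset = set(nodes)
        indeg = {n: 0 for n in nodes}
        dependents: dict[str, list[str]] = {n: [] for n in nodes}
        for n in nodes:
            for d in self._deps[n]:
                if d in nodeset:
                    indeg[n] += 1
                    dependents[d].append(n)
        ready = [n for n in nodes if indeg[n] == 0]
        heapq.heapify(ready)
        order: list[str] = []
        while ready:
            n = heapq.heappop(ready)
            order.append(n)
            for m in dependents[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    heapq.heappush(ready, m)
        if len(order) != len(nodes):
            cycle = sorted(n for n in nodes if indeg[n] > 0)
            raise StructuralError(
                f"cyclic auxiliary/flow dependency involving: {', '.join(cycle)}"
            )
        return tuple(order)

    # -- evaluation ---------------------------------------------------------

    @property
    def stocks(self) -> tuple[str, ...]:
        return tuple(sorted(n for n, r in self.variables.items() if r == "stock"))

    @property
    def constants(self) -> tuple[str, ...]:
        return tuple(sorted(n for n, r in self.variables.items() if r == "constant"))

    def check_state(self, state: Mapping[str, float]) -> None:
        missing = [n for n in (*self.stocks, *self.constants) if n not in state]
        if missing:
            raise ValidationError(f"state is missing values for: {', '.join(missing)}")

    def evaluate(self, state: Mapping[str, float],
                 overrides: Mapping[str, float] | None = None) -> dict[str, float]:
        """Compute every auxiliary and flow from stock/constant values.

        ``overrides`` pins named auxiliaries/flows to given values instead
        of recomputing them (used by the edge-sign perturbation check).
        """
        self.check_state(state)
        ns = dict(self._namespace_base)
        ns.update(state)
        if overrides:
            ns.update(overrides)
        for name in self._order:
            if overrides and name in overrides:
                continue
            ns[name] = eval(self._codes[name], {"__builtins__": {}}, ns)
        return {k: float(ns[k]) for k in self.variables}

    def net_flow_value(self, stock: str, full_state: Mapping[str, float]) -> float:
        ins, outs = self.net_flow[stock]
        return sum(full_state[f] for f in ins) - sum(full_state[f] for f in outs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": dict(self.variables),
            "equations": dict(self.equations),
            "net_flow": {s: [list(i), list(o)] for s, (i, o) in self.net_flow.items()},
            "edges": [[e.source, e.target, e.sign, e.delayed] for e in self.edges],
            "tables": {k: {"xs": list(t.xs), "ys": list(t.ys)} for k, t in self.tables.items()},
            "bounded": sorted(self.bounded),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelGraph":
        return cls(
            variables=dict(d["variables"]),
            equations=dict(d.get("equations", {})),
            net_flow={s: (tuple(i), tuple(o)) for s, (i, o) in d.get("net_flow", {}).items()},
            edges=tuple(Edge(s, t, sg, bool(dl)) for s, t, sg, dl in d.get("edges", [])),
            tables={k: TableFunction(v["xs"], v["ys"]) for k, v in d.get("tables", {}).items()},
            bounded=frozenset(d.get("bounded", [])),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "ModelGraph":
        return cls.from_dict(json.loads(source))


# --------------------------------------------------------------------------
# Run configuration and trajectories
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Simulation grid: start time, duration and step, all in weeks."""

    horizon: float
    dt: float = 0.125
    t0: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.horizon <= 0:
            raise ParameterError(f"horizon must be positive, got {self.horizon}")
        ratio = self.horizon / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError(
                f"horizon ({self.horizon}) must be an integer multiple of dt ({self.dt})"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_steps + 1) * self.dt


@dataclass
class TrajectorySet:
    """Multi-variable time series on a common, strictly increasing grid."""

    times: np.ndarray
    series: dict[str, np.ndarray]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValidationError("times must be a nonempty 1-D grid")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        clean = {}
        for name, vals in self.series.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape != self.times.shape:
                raise ValidationError(
                    f"series '{name}' has length {arr.shape} != grid {self.times.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"series '{name}' contains non-finite values")
            clean[name] = arr
        self.series = clean

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.series)

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.series:
            raise KeyError(f"no series named '{name}'")
        return self.series[name]

    def subset(self, names: Iterable[str]) -> "TrajectorySet":
        names = list(names)
        missing = [n for n in names if n not in self.series]
        if missing:
            raise ValidationError(f"missing series: {', '.join(missing)}")
        return TrajectorySet(self.times.copy(), {n: self.series[n].copy() for n in names})

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"week": self.times, **self.series})


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple cycle of the causal edge set with its polarity.

    A loop is *reinforcing* when the number of negative edges on the cycle
    is even, *balancing* when it is odd.
    """

    cycle: tuple[str, ...]
    polarity: str
    label: str | None = None

    @property
    def length(self) -> int:
        return len(self.cycle)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------


def euler_step(model: ModelGraph, state: Mapping[str, float], dt: float) -> dict[str, float]:
    """Advance the model one explicit-Euler step of length ``dt``.

    ``state`` must assign values to every stock and constant.  Auxiliaries
    and flows are evaluated at the current time in topological order, then
    each stock is updated as ``stock + dt * (inflows - outflows)``.
    Bounded stocks are clamped to [0, 1].  Returns the new state
    (stocks and constants).
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    full = model.evaluate(state)
    new_state: dict[str, float] = {c: float(state[c]) for c in model.constants}
    for stock in model.stocks:
        value = float(state[stock]) + dt * model.net_flow_value(stock, full)
        if stock in model.bounded:
            value = min(1.0, max(0.0, value))
        new_state[stock] = value
    return new_state


def run_simulation(model: ModelGraph, config: RunConfig,
                   initial: Mapping[str, float]) -> TrajectorySet:
    """Simulate the model on the grid of ``config``.

    Records every variable (stocks, constants, flows and auxiliaries) at
    each of the ``horizon/dt + 1`` grid points.  The result is a pure
    function of ``(model, config, initial)``.
    """
    model.check_state(initial)
    times = config.times
    record: dict[str, list[float]] = {name: [] for name in model.variables}
    state = {k: float(initial[k]) for k in (*model.stocks, *model.constants)}
    for i in range(config.n_steps + 1):
        full = model.evaluate(state)
        for name in record:
            record[name].append(full[name])
        if i < config.n_steps:
            state = euler_step(model, state, config.dt)
    return TrajectorySet(times, {k: np.asarray(v) for k, v in record.items()})


# --------------------------------------------------------------------------
# Feedback loops
# --------------------------------------------------------------------------


def _canonical_rotation(cycle: Sequence[str]) -> tuple[str, ...]:
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[k:]) + tuple(cycle[:k])


def enumerate_feedback_loops(model: ModelGraph,
                             max_len: int | None = None) -> list[FeedbackLoop]:
    """All simple cycles of the declared causal edge set, with polarity.

    Cycles are reported in canonical form (lexicographically smallest
    rotation) and sorted by length then lexicographically, so the output
    order is deterministic.  Acyclic graphs yield an empty list.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(model.variables)
    sign_of: dict[tuple[str, str], int] = {}
    for e in model.edges:
        graph.add_edge(e.source, e.target)
        sign_of[(e.source, e.target)] = -1 if e.sign == "-" else 1
    loops = []
    for cycle in nx.simple_cycles(graph, length_bound=max_len):
        canon = _canonical_rotation(cycle)
        product = 1
        for a, b in zip(canon, canon[1:] + canon[:1]):
            product *= sign_of[(a, b)]
        polarity = "reinforcing" if product > 0 else "balancing"
        loops.append(FeedbackLoop(cycle=canon, polarity=polarity))
    loops.sort(key=lambda lp: (lp.length, lp.cycle))
    return loops


# --------------------------------------------------------------------------
# Edge-sign consistency
# --------------------------------------------------------------------------


def _perturbed_target_value(model: ModelGraph, state: dict[str, float],
                            source: str, target: str, value: float) -> float:
    """Target value (or net flow for stock targets) with ``source`` pinned."""
    role = model.variables[source]
    if role in ("stock", "constant"):
        pstate = dict(state)
        pstate[source] = value
        full = model.evaluate(pstate)
    else:
        full = model.evaluate(state, overrides={source: value})
    if model.variables[target] == "stock":
        return model.net_flow_value(target, full)
    return full[target]


def check_edge_signs(model: ModelGraph, reference_state: Mapping[str, float],
                     eps: float = 1e-3, tol: float = 1e-9) -> dict[Edge, float]:
    """Check declared edge polarities by finite-difference perturbation.

    Each edge's source is perturbed by ``±eps`` at the reference state;
    auxiliaries downstream of the source are re-evaluated and the response
    of the target (its equation, or its net flow for a stock target) gives
    the numerical partial derivative.  A derivative of magnitude below
    ``tol`` is *consistent* with any declared sign (weak monotonicity, e.g.
    the momentarily inactive branch of a ``min``); a nonzero derivative of
    opposite sign raises :class:`StructuralError`.

    Returns the measured derivative per edge.
    """
    model.check_state(reference_state)
    state = {k: float(reference_state[k])
             for k in (*model.stocks, *model.constants)}
    full = model.evaluate(state)
    measured: dict[Edge, float] = {}
    for edge in model.edges:
        base = full[edge.source]
        hi = _perturbed_target_value(model, state, edge.source, edge.target, base + eps)
        lo = _perturbed_target_value(model, state, edge.source, edge.target, base - eps)
        deriv = (hi - lo) / (2 * eps)
        measured[edge] = deriv
        if abs(deriv) > tol:
            expected = 1 if edge.sign == "+" else -1
            if (deriv > 0) != (expected > 0):
                raise StructuralError(
                    f"edge {edge.source} -> {edge.target} declared '{edge.sign}' "
                    f"but numerical partial derivative is {deriv:+.3g}"
                )
    return measured
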