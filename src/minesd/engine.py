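"""Generic discrete-time stock-flow system-dynamics engine.

A model is declared as four collections — constants, auxiliaries, rates and
stocks — and integrated with fixed-step explicit Euler, the classic
DYNAMO/Vensim level–rate scheme::

    stock.K = stock.J + DT * (sum of inflows.JK - sum of outflows.JK)

Rates and auxiliaries are arithmetic expressions (``+ - * /`` and
parentheses) over the names of constants, stocks and other auxiliaries; they
are evaluated from the state at the start of each step.  There is no
randomness anywhere in the engine: two runs with identical inputs produce
bit-identical trajectories.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ConstantDef",
    "AuxiliaryDef",
    "RateDef",
    "StockDef",
    "ModelSpec",
    "SimConfig",
    "Trajectory",
    "ExpressionError",
    "ModelValidationError",
    "EvaluationError",
    "parse_expression",
    "validate_model",
    "evaluate_step_values",
    "euler_step",
    "simulate",
]


class ExpressionError(ValueError):
    """An arithmetic expression could not be parsed or uses forbidden syntax."""


class ModelValidationError(ValueError):
    """A model with a non-empty diagnostics list was passed where a valid one is required."""

    def __init__(self, diagnostics: Iterable[str]):
        self.diagnostics = list(diagnostics)
        super().__init__("invalid model: " + "; ".join(self.diagnostics))


class EvaluationError(ArithmeticError):
    """Numerical failure (e.g. division by zero) while evaluating a named variable."""

    def __init__(self, variable: str, detail: str, time: float | None = None):
        self.variable = variable
        self.time = time
        msg = f"error evaluating {variable!r}: {detail}"
        if time is not None:
            msg += f" (at time {time:g})"
        super().__init__(msg)


_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)
_ALLOWED_UNARY = (ast.UAdd, ast.USub)


def parse_expression(text: str) -> tuple["ast.Expression", frozenset[str]]:
    """Parse an arithmetic expression, returning the AST and the referenced names.

    Only ``+ - * /``, unary sign, parentheses, numeric literals and bare
    variable names are accepted; anything else raises :class:`ExpressionError`.
    """
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError("empty expression")
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse {text!r}: {exc.msg}") from exc
    names: set[str] = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Expression):
            continue
        if isinstance(node, ast.BinOp):
            if not isinstance(node.op, _ALLOWED_BINOPS):
                raise ExpressionError(f"operator not allowed in {text!r}")
            continue
        if isinstance(node, ast.UnaryOp):
            if not isinstance(node.op, _ALLOWED_UNARY):
                raise ExpressionError(f"operator not allowed in {text!r}")
            continue
        if isinstance(node, (*_ALLOWED_BINOPS, *_ALLOWED_UNARY, ast.Load)):
            continue
        if isinstance(node, ast.Name):
            if not isinstance(node.ctx, ast.Load):
                raise ExpressionError(f"assignment not allowed in {text!r}")
            names.add(node.id)
            continue
        if isinstance(node, ast.Constant):
            if isinstance(node.value, bool) or not isinstance(node.value, (int, float)):
                raise ExpressionError(f"non-numeric literal in {text!r}")
            continue
        raise ExpressionError(
            f"unsupported syntax {type(node).__name__!r} in {text!r}"
        )
    return tree, frozenset(names)


def _compile(tree: "ast.Expression") -> "code":  # type: ignore[valid-type]
    return compile(tree, "<expression>", "eval")


@dataclass(frozen=True)
class ConstantDef:
    """A named constant (a Table-style model parameter)."""

    name: str
    value: float
    unit: str = ""


@dataclass(frozen=True)
class AuxiliaryDef:
    """An algebraic variable recomputed each step from constants, stocks and auxiliaries."""

    name: str
    expression: str


@dataclass(frozen=True)
class RateDef:
    """A flow feeding (``inflow``) or draining (``outflow``) a single stock."""

    name: str
    expression: str
    direction: str  # "inflow" | "outflow"
    stock: str


@dataclass(frozen=True)
class StockDef:
    """A level variable, integrated over time from its initial value."""

    name: str
    initial: float
    unit: str = ""


def _as_tuple(items) -> tuple:
    return tuple(items) if items is not None else ()


@dataclass(frozen=True)
class ModelSpec:
    """Declarative stock-flow model: constants, auxiliaries, rates, stocks."""

    constants: tuple[ConstantDef, ...] = ()
    auxiliaries: tuple[AuxiliaryDef, ...] = ()
    rates: tuple[RateDef, ...] = ()
    stocks: tuple[StockDef, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "constants", _as_tuple(self.constants))
        object.__setattr__(self, "auxiliaries", _as_tuple(self.auxiliaries))
        object.__setattr__(self, "rates", _as_tuple(self.rates))
        object.__setattr__(self, "stocks", _as_tuple(self.stocks))

    @property
    def all_names(self) -> tuple[str, ...]:
        return tuple(
            d.name
            for group in (self.constants, self.auxiliaries, self.rates, self.stocks)
            for d in group
        )

    @property
    def stock_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.stocks)

    @classmethod
    def merge(cls, *fragments: "ModelSpec") -> "ModelSpec":
        """Union of fragments; identical duplicate definitions collapse.

        A name defined twice with *different* definitions (e.g. the same
        constant with two values) is a collision and raises ``ValueError``.
        """
        seen: dict[str, object] = {}
        groups: dict[str, list] = {"constants": [], "auxiliaries": [], "rates": [], "stocks": []}
        for frag in fragments:
            for kind in groups:
                for d in getattr(frag, kind):
                    if d.name in seen:
                        if seen[d.name] != d:
                            raise ValueError(
                                f"name collision while merging fragments: {d.name!r} "
                                f"defined as both {seen[d.name]!r} and {d!r}"
                            )
                        continue
                    seen[d.name] = d
                    groups[kind].append(d)
        return cls(**{k: tuple(v) for k, v in groups.items()})


@dataclass(frozen=True)
class SimConfig:
    """Simulation grid: fixed-step explicit Euler from initial_time to final_time."""

    initial_time: float = 0
    final_time: float = 24
    dt: float = 1.0
    method: str = "euler"

    def __post_init__(self):
        if self.method != "euler":
            raise ValueError(f"only the Euler method is supported, got {self.method!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.final_time <= self.initial_time:
            raise ValueError("final_time must exceed initial_time")
        n = (self.final_time - self.initial_time) / self.dt
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("(final_time - initial_time)/dt must be a positive integer")

    @property
    def n_steps(self) -> int:
        return int(round((self.final_time - self.initial_time) / self.dt))


@dataclass
class Trajectory:
    """Time-indexed series of every model variable over the simulation horizon.

    ``series`` maps variable name to an array of length ``n_steps + 1``; stocks
    are recorded at every grid point, rates and auxiliaries as evaluated from
    the state at that grid point (for interior points, the step-start values).
    """

    times: np.ndarray
    series: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times}
        data.update(self.series)
        return pd.DataFrame(data)


def validate_model(spec: ModelSpec) -> list[str]:
    """Return one diagnostic string per violation; a valid model yields ``[]``.

    Never raises: malformed expression text yields a parse diagnostic.
    """
    diags: list[str] = []
    seen: set[str] = set()
    for name in spec.all_names:
        if name in seen:
            diags.append(f"duplicate name: {name!r}")
        seen.add(name)
    for c in spec.constants:
        if not np.isfinite(c.value):
            diags.append(f"constant {c.name!r} has non-finite value {c.value!r}")
    for s in spec.stocks:
        if not np.isfinite(s.initial):
            diags.append(f"stock {s.name!r} has non-finite initial value {s.initial!r}")

    known = set(spec.all_names)
    aux_names = {a.name for a in spec.auxiliaries}
    aux_deps: dict[str, set[str]] = {}
    for d in (*spec.auxiliaries, *spec.rates):
        kind = "auxiliary" if isinstance(d, AuxiliaryDef) else "rate"
        try:
            _, refs = parse_expression(d.expression)
        except ExpressionError as exc:
            diags.append(f"{kind} {d.name!r}: {exc}")
            continue
        for ref in sorted(refs - known):
            diags.append(f"{kind} {d.name!r} references undefined name {ref!r}")
        if kind == "auxiliary":
            aux_deps[d.name] = refs & aux_names
    for r in spec.rates:
        if r.direction not in ("inflow", "outflow"):
            diags.append(f"rate {r.name!r} has invalid direction {r.direction!r}")
        if r.stock not in {s.name for s in spec.stocks}:
            diags.append(f"rate {r.name!r} targets undefined stock {r.stock!r}")
    try:
        tuple(TopologicalSorter(aux_deps).static_order())
    except CycleError as exc:
        cycle = ", ".join(repr(n) for n in exc.args[1])
        diags.append(f"auxiliary dependency cycle: {cycle}")
    return diags


class _CompiledModel:
    """Pre-compiled expressions and auxiliary evaluation order for a valid spec."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.const_env = {c.name: float(c.value) for c in spec.constants}
        aux_names = {a.name for a in spec.auxiliaries}
        deps = {}
        self.code: dict[str, object] = {}
        for a in spec.auxiliaries:
            tree, refs = parse_expression(a.expression)
            self.code[a.name] = _compile(tree)
            deps[a.name] = refs & aux_names
        order = tuple(TopologicalSorter(deps).static_order())
        self.aux_order = order
        for r in spec.rates:
            tree, _ = parse_expression(r.expression)
            self.code[r.name] = _compile(tree)
        self.inflows: dict[str, list[str]] = {s.name: [] for s in spec.stocks}
        self.outflows: dict[str, list[str]] = {s.name: [] for s in spec.stocks}
        for r in spec.rates:
            (self.inflows if r.direction == "inflow" else self.outflows)[r.stock].append(r.name)

    def step_values(
        self, stock_values: Mapping[str, float], time: float | None = None
    ) -> dict[str, float]:
        env = dict(self.const_env)
        env.update(stock_values)
        out: dict[str, float] = {}
        for name in self.aux_order:
            try:
                value = eval(self.code[name], {"__builtins__": {}}, env)
            except ZeroDivisionError:
                raise EvaluationError(name, "division by zero", time) from None
            env[name] = out[name] = float(value)
        for r in self.spec.rates:
            try:
                value = eval(self.code[r.name], {"__builtins__": {}}, env)
            except ZeroDivisionError:
                raise EvaluationError(r.name, "division by zero", time) from None
            out[r.name] = float(value)
        return out

    def advance(
        self, stock_values: Mapping[str, float], dt: float, time: float | None = None
    ) -> dict[str, float]:
        vals = self.step_values(stock_values, time)
        nxt = {}
        for s in self.spec.stocks:
            net = sum(vals[n] for n in self.inflows[s.name]) - sum(
                vals[n] for n in self.outflows[s.name]
            )
            nxt[s.name] = stock_values[s.name] + dt * net
        return nxt


def _require_valid(spec: ModelSpec) -> None:
    diags = validate_model(spec)
    if diags:
        raise ModelValidationError(diags)


def evaluate_step_values(
    spec: ModelSpec, stock_values: Mapping[str, float]
) -> dict[str, float]:
    """Evaluate every auxiliary (in dependency order) and rate at the given state."""
    _require_valid(spec)
    return _CompiledModel(spec).step_values(dict(stock_values))


def euler_step(
    spec: ModelSpec, stock_values: Mapping[str, float], dt: float
) -> dict[str, float]:
    """One explicit Euler step: next = current + dt * (inflows - outflows)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    _require_valid(spec)
    return _CompiledModel(spec).advance(dict(stock_values), dt)


def simulate(spec: ModelSpec, config: SimConfig | None = None) -> Trajectory:
    """Integrate the model over the configured grid.

    Records every stock, auxiliary and rate at all ``n_steps + 1`` grid points.
    Evaluation errors are re-raised with the time at which they occurred.
    """
    if config is None:
        config = SimConfig()
    _require_valid(spec)
    cm = _CompiledModel(spec)
    n = config.n_steps
    times = config.initial_time + config.dt * np.arange(n + 1, dtype=float)
    var_names = [s.name for s in spec.stocks]
    var_names += [a.name for a in spec.auxiliaries]
    var_names += [r.name for r in spec.rates]
    data = {name: np.empty(n + 1, dtype=float) for name in var_names}
    current = {s.name: float(s.initial) for s in spec.stocks}
    for k in range(n + 1):
        vals = cm.step_values(current, time=times[k])
        for name in current:
            data[name][k] = current[name]
        for name, v in vals.items():
            data[name][k] = v
        if k < n:
            current = cm.advance(current, config.dt, time=times[k])
    for name, arr in data.items():
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise EvaluationError(name, "non-finite value", times[bad])
    return Trajectory(times=times, series=data)
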