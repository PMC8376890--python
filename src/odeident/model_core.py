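"""Symbolic state-space ODE models.

A model is written in the standard affine-in-input state-space form

    dx/dt = f0(x, theta) + sum_i u_i(t) * f_i(x, theta),   x(0) = x0,
    y(t)  = h(x, theta),

with states ``x`` (dimension n), system parameters ``theta`` (dimension p),
input signals ``u_1..u_k`` and measured outputs ``y`` (dimension m).  Initial
conditions may be numeric, zero, tied to parameters through an expression
(e.g. ``x2(0) = p1/p3``), or unknown; unknown initial conditions are promoted
to extra parameters, so the full unknown vector has up to ``p + n`` entries.

The ordering of states, parameters and outputs is stable and defines the
row/column ordering of every downstream matrix (sensitivity matrix columns,
Jacobi matrix columns, singular-vector components).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import sympy as sp
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

__all__ = [
    "OdeModel",
    "NominalAssignment",
    "validate_model",
    "promote_initial_conditions",
    "invariant_zero_states",
    "parse_model",
    "parse_model_file",
    "serialize_model",
]

_TRANSFORMS = standard_transformations + (convert_xor,)

#: functions permitted inside model expressions
_ALLOWED_FUNCS = {"exp": sp.exp, "log": sp.log, "pow": sp.Pow, "sqrt": sp.sqrt}


def _sym(name: str) -> sp.Symbol:
    return sp.Symbol(name)


@dataclass(frozen=True)
class OdeModel:
    """An ODE model in standard state-space form.

    Parameters
    ----------
    states
        Ordered state symbols ``x_1 .. x_n``.
    params
        Ordered system-parameter symbols ``theta_1 .. theta_p``.
    drift
        The ``n`` expressions of the drift vector field ``f0``.
    outputs
        The ``m >= 1`` output expressions ``h``.
    initial_conditions
        One entry per state: a number, zero, a free symbol (marking the
        initial value unknown) or an expression in the parameters.
    inputs
        Input placeholder symbols ``u_1 .. u_k``; their time courses are
        bound only in the numeric layer.
    input_fields
        ``k`` vector fields ``f_i``, one per input, each of length ``n``.
    constants
        Named fixed numeric quantities usable in any expression.
    ic_params
        Promoted initial-condition parameters, in state order.  Populated by
        :func:`promote_initial_conditions`; the full unknown vector is
        ``params + ic_params``.
    """

    name: str
    states: tuple[sp.Symbol, ...]
    params: tuple[sp.Symbol, ...]
    drift: tuple[sp.Expr, ...]
    outputs: tuple[sp.Expr, ...]
    initial_conditions: tuple[sp.Expr, ...]
    inputs: tuple[sp.Symbol, ...] = ()
    input_fields: tuple[tuple[sp.Expr, ...], ...] = ()
    constants: tuple[tuple[sp.Symbol, float], ...] = ()
    ic_params: tuple[sp.Symbol, ...] = ()

    # -- dimensions ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def p(self) -> int:
        return len(self.params)

    @property
    def m(self) -> int:
        return len(self.outputs)

    @property
    def k(self) -> int:
        return len(self.inputs)

    @property
    def unknowns(self) -> tuple[sp.Symbol, ...]:
        """Full unknown vector: system parameters first, then promoted
        initial-condition parameters in state order."""
        return self.params + self.ic_params

    @property
    def constants_dict(self) -> dict[sp.Symbol, float]:
        return dict(self.constants)

    def ic_of(self, state: sp.Symbol | str) -> sp.Expr:
        s = _sym(state) if isinstance(state, str) else state
        return self.initial_conditions[self.states.index(s)]

    def state_of_ic_param(self, sym: sp.Symbol) -> sp.Symbol:
        """State whose initial condition is the promoted parameter ``sym``."""
        for x, ic in zip(self.states, self.initial_conditions):
            if ic == sym:
                return x
        raise KeyError(f"{sym} is not a promoted initial-condition parameter")

    def rhs(self, u_values: Mapping[sp.Symbol, sp.Expr] | None = None) -> tuple[sp.Expr, ...]:
        """Full right-hand side ``f0 + sum_i u_i f_i`` with ``u_i`` symbolic
        (or substituted from *u_values*)."""
        total = list(self.drift)
        for u, field in zip(self.inputs, self.input_fields):
            uval = u if u_values is None else u_values.get(u, u)
            total = [t + uval * fi for t, fi in zip(total, field)]
        return tuple(sp.expand(t) for t in total)


@dataclass(frozen=True)
class NominalAssignment:
    """Numeric point at which the numeric analysis is evaluated: one finite
    value per unknown (system parameter or promoted initial condition)."""

    values: tuple[tuple[sp.Symbol, float], ...]
    provenance: str = "user-given"  # or "seeded-random"
    seed: int | None = None

    @property
    def as_dict(self) -> dict[sp.Symbol, float]:
        return dict(self.values)

    def value_of(self, sym: sp.Symbol) -> float:
        return self.as_dict[sym]

    @staticmethod
    def from_dict(values: Mapping[sp.Symbol, float], provenance: str = "user-given",
                  seed: int | None = None) -> "NominalAssignment":
        return NominalAssignment(tuple(values.items()), provenance, seed)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: OdeModel) -> list[str]:
    """Check the structural invariants of a model.

    Returns an empty list iff the model is well formed; otherwise one
    diagnostic string per violation, each naming the offending expression or
    symbol.  Never raises.
    """
    diags: list[str] = []
    n = model.n

    if len(model.drift) != n:
        diags.append(f"drift length {len(model.drift)} != n = {n}")
    for i, field in enumerate(model.input_fields):
        if len(field) != n:
            diags.append(f"input field {i + 1} has length {len(field)} != n = {n}")
    if len(model.input_fields) != model.k:
        diags.append(
            f"{model.k} input symbols but {len(model.input_fields)} input fields")
    if model.m < 1:
        diags.append("model must declare at least one output")
    if len(model.initial_conditions) != n:
        diags.append(
            f"{len(model.initial_conditions)} initial conditions for {n} states")

    if len(set(model.states)) != n:
        diags.append("duplicate state symbols")
    if len(set(model.unknowns)) != len(model.unknowns):
        diags.append("duplicate parameter symbols")

    allowed = set(model.states) | set(model.params) | set(model.ic_params)
    allowed |= {c for c, _ in model.constants}
    # free symbols used as unknown-IC markers are legal inside expressions
    # (e.g. a drift term k_t*EpoR0 where EpoR0 = EpoR(0)):
    for ic in model.initial_conditions:
        allowed |= sp.sympify(ic).free_symbols - set(model.states)

    def check(expr: sp.Expr, where: str) -> None:
        stray = sp.sympify(expr).free_symbols - allowed
        for s in sorted(stray, key=str):
            diags.append(f"stray symbol {s} in {where}: {expr}")

    for i, e in enumerate(model.drift):
        check(e, f"drift[{i}]")
    for j, field in enumerate(model.input_fields):
        for i, e in enumerate(field):
            check(e, f"input_field[{j}][{i}]")
    for i, e in enumerate(model.outputs):
        check(e, f"output[{i}]")
    for i, e in enumerate(model.initial_conditions):
        stray = sp.sympify(e).free_symbols - set(model.params) - {
            c for c, _ in model.constants}
        # an IC may be a single unknown marker symbol, but not an expression
        # mixing undeclared symbols with others
        if stray and not (len(sp.sympify(e).free_symbols) == 1 and e.is_Symbol):
            for s in sorted(stray, key=str):
                diags.append(f"stray symbol {s} in initial_conditions[{i}]: {e}")
        if e.is_Symbol and e in set(model.states):
            diags.append(f"initial_conditions[{i}] refers to state {e}")
    return diags


# ---------------------------------------------------------------------------
# promotion of unknown initial conditions
# ---------------------------------------------------------------------------

def promote_initial_conditions(model: OdeModel,
                               unknown_ics: Sequence[str] | set[str]) -> OdeModel:
    """Promote the named states' initial conditions to unknown parameters.

    Each named state gets one IC parameter: the symbol already stored in its
    initial-condition slot if that slot holds a plain unknown marker, else a
    fresh symbol ``<state>0``.  The unknown vector of the result is
    ``[system params..., IC params in state order]``; promoting every initial
    condition yields dimension ``p + n``.  Idempotent for a fixed set.
    """
    names = {s if isinstance(s, str) else str(s) for s in unknown_ics}
    state_names = [str(s) for s in model.states]
    for nm in sorted(names):
        if nm not in state_names:
            raise ValueError(f"unknown state name in unknown_ics: {nm!r}")

    ic_params: list[sp.Symbol] = []
    new_ics = list(model.initial_conditions)
    taken = set(model.states) | set(model.params) | {c for c, _ in model.constants}
    for i, (x, ic) in enumerate(zip(model.states, model.initial_conditions)):
        if str(x) not in names:
            continue
        if ic.is_Symbol and ic not in taken:
            sym = ic
        else:
            sym = _sym(f"{x}0")
            if sym in taken:
                sym = _sym(f"{x}_ic")
            new_ics[i] = sym
        ic_params.append(sym)
    return dataclasses.replace(
        model,
        initial_conditions=tuple(new_ics),
        ic_params=tuple(ic_params),
    )


# ---------------------------------------------------------------------------
# invariant-zero analysis
# ---------------------------------------------------------------------------

def invariant_zero_states(model: OdeModel, zero_states) -> set[sp.Symbol]:
    """Largest subset Z of *zero_states* such that substituting ``x_Z = 0``
    (and zeroing the promoted IC parameters of those states, which may appear
    in the dynamics) makes every ``dx_j/dt``, ``j in Z``, identically zero —
    for the drift and for every input field, so the states stay at zero for
    all time regardless of the inputs."""
    Z = {s if isinstance(s, sp.Symbol) else _sym(str(s)) for s in zero_states}
    Z &= set(model.states)
    idx = {x: i for i, x in enumerate(model.states)}
    promoted = set(model.ic_params)
    while True:
        subs: dict = {x: sp.S.Zero for x in Z}
        for x in Z:
            ic = model.initial_conditions[idx[x]]
            if ic.is_Symbol and ic in promoted:
                subs[ic] = sp.S.Zero
        drop = set()
        for x in Z:
            i = idx[x]
            exprs = [model.drift[i]] + [f[i] for f in model.input_fields]
            if any(sp.expand(sp.sympify(e).xreplace(subs)) != 0 for e in exprs):
                drop.add(x)
        if not drop:
            return Z
        Z -= drop


# ---------------------------------------------------------------------------
# plain-text model format
# ---------------------------------------------------------------------------
# Sections (order free, one per line or indented blocks):
#   states: x1 x2
#   parameters: p1 p2 p3
#   constants:          (optional)   c1 = 1.0
#   inputs: u1          (optional)
#   odes:               x1 = p1*x1^2 + p2*x1*x2   (one per state, in order)
#   outputs:            y1 = x1
#   initial_conditions: x1 = ?x10 | x2 = 0 | x2 = p1/p3 | x1 = 1.3
# Expression grammar: + - * / ^ ( ), function names pow/exp/log/sqrt.
# `?name` marks an unknown initial condition with marker symbol `name`.

def serialize_model(model: OdeModel) -> str:
    lines = [f"# model {model.name}", f"name: {model.name}"]
    lines.append("states: " + " ".join(map(str, model.states)))
    lines.append("parameters: " + " ".join(map(str, model.params)))
    if model.constants:
        lines.append("constants:")
        for c, v in model.constants:
            lines.append(f"  {c} = {v!r}")
    if model.inputs:
        lines.append("inputs: " + " ".join(map(str, model.inputs)))
    lines.append("odes:")
    for x, e in zip(model.states, model.rhs()):
        lines.append(f"  {x} = {sp.sstr(e)}")
    lines.append("outputs:")
    for i, e in enumerate(model.outputs):
        lines.append(f"  y{i + 1} = {sp.sstr(e)}")
    lines.append("initial_conditions:")
    unknown_markers = {ic for x, ic in zip(model.states, model.initial_conditions)
                       if ic.is_Symbol and ic not in set(model.params)}
    for x, ic in zip(model.states, model.initial_conditions):
        if ic in unknown_markers:
            lines.append(f"  {x} = ?{ic}")
        else:
            lines.append(f"  {x} = {sp.sstr(ic)}")
    return "\n".join(lines) + "\n"


def _parse_expr(text: str, local: dict) -> sp.Expr:
    expr = parse_expr(text, local_dict={**local, **_ALLOWED_FUNCS},
                      transformations=_TRANSFORMS, evaluate=True)
    return sp.sympify(expr)


def parse_model(text: str) -> OdeModel:
    """Parse the plain-text model format; inverse of :func:`serialize_model`
    up to symbolic equivalence of expressions."""
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        m = re.match(r"^(\w+):\s*(.*)$", line) if not line.startswith(" ") else None
        if m:
            current = m.group(1)
            sections.setdefault(current, [])
            if m.group(2):
                sections[current].append(m.group(2))
        elif current is not None:
            sections[current].append(line.strip())
        else:
            raise ValueError(f"model file: content before any section: {line!r}")

    def words(key: str) -> list[str]:
        return " ".join(sections.get(key, [])).split()

    name = " ".join(sections.get("name", ["model"]))
    states = tuple(_sym(w) for w in words("states"))
    params = tuple(_sym(w) for w in words("parameters"))
    inputs = tuple(_sym(w) for w in words("inputs"))
    constants: list[tuple[sp.Symbol, float]] = []
    for line in sections.get("constants", []):
        lhs, rhs = (t.strip() for t in line.split("=", 1))
        constants.append((_sym(lhs), float(rhs)))

    local = {str(s): s for s in states}
    local.update({str(s): s for s in params})
    local.update({str(s): s for s in inputs})
    local.update({str(c): c for c, _ in constants})

    def split_assign(line: str, what: str) -> tuple[str, str]:
        if "=" not in line:
            raise ValueError(f"model file: malformed {what} line: {line!r}")
        lhs, rhs = line.split("=", 1)
        return lhs.strip(), rhs.strip()

    ode_map: dict[sp.Symbol, sp.Expr] = {}
    for line in sections.get("odes", []):
        lhs, rhs = split_assign(line, "ode")
        ode_map[_sym(lhs)] = _parse_expr(rhs, local)
    missing = [str(x) for x in states if x not in ode_map]
    if missing:
        raise ValueError(f"model file: missing odes for states {missing}")

    # split the full RHS into drift + sum_i u_i f_i (affine in the inputs)
    drift: list[sp.Expr] = []
    fields: list[list[sp.Expr]] = [[] for _ in inputs]
    for x in states:
        expr = sp.expand(ode_map[x])
        rest = expr
        for j, u in enumerate(inputs):
            coeff = sp.expand(sp.diff(expr, u))
            if coeff.free_symbols & set(inputs):
                raise ValueError(
                    f"model file: ode for {x} is not affine in input {u}: {expr}")
            fields[j].append(coeff)
            rest = sp.expand(rest - coeff * u)
        if rest.free_symbols & set(inputs):
            raise ValueError(f"model file: ode for {x} not affine in inputs: {expr}")
        drift.append(rest)

    outputs = tuple(_parse_expr(split_assign(line, "output")[1], local)
                    for line in sections.get("outputs", []))

    ics: list[sp.Expr] = []
    ic_lines = {split_assign(line, "initial condition")[0]:
                split_assign(line, "initial condition")[1]
                for line in sections.get("initial_conditions", [])}
    for x in states:
        raw = ic_lines.get(str(x), "0")
        if raw.startswith("?"):
            ics.append(_sym(raw[1:]))
        else:
            ics.append(_parse_expr(raw, local))

    return OdeModel(
        name=name, states=states, params=params, drift=tuple(drift),
        outputs=outputs, initial_conditions=tuple(ics), inputs=inputs,
        input_fields=tuple(tuple(f) for f in fields),
        constants=tuple(constants),
    )


def parse_model_file(path: str) -> OdeModel:
    with open(path) as fh:
        return parse_model(fh.read())
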