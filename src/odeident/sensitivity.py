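"""Forward sensitivity system and the stacked sensitivity matrix.

The numeric screening step integrates the variational (forward sensitivity)
equations alongside the state equations,

    d/dt (dx/dtheta) = (dF/dx) (dx/dtheta) + dF/dtheta,
    dy/dtheta        = (dh/dx) (dx/dtheta) + dh/dtheta,

where ``F = f0 + sum_i u_i(t) f_i`` is the full right-hand side, and stacks
the output sensitivities ``dy/dtheta`` evaluated on a time grid
``t_0 .. t_N`` into the sensitivity matrix ``S`` of shape
``m (N+1) x q`` (``q`` = number of unknowns of the promoted model).  Full
column rank of ``S`` is a sufficient condition for local structural
identifiability at the nominal point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.integrate
import sympy as sp

from .model_core import NominalAssignment, OdeModel

__all__ = [
    "ExperimentConfig",
    "SensitivityMatrix",
    "SensitivitySystem",
    "IntegrationError",
    "assemble_sensitivity_system",
    "integrate_sensitivities",
    "build_sensitivity_matrix",
    "sensitivity_matrix_to_csv",
]


class IntegrationError(RuntimeError):
    """Raised when the forward integration fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Time grid, input signals and integration settings for the numeric step.

    ``input_signals`` holds one spec per model input:
    ``("constant", v)``, ``("piecewise", (t1, t2, ...), (v0, v1, ...))``
    (value ``v_j`` on ``[t_j, t_{j+1})``) or
    ``("sines", (a1, ...), (w1, ...))`` / ``("sines", amps, freqs, offset)``
    meaning ``offset + sum_i a_i sin(w_i t)``.  Inputs without a spec default
    to the constant signal 1.
    """

    t0: float = 0.0
    t_end: float = 10.0
    n_points: int = 101
    input_signals: tuple = ()
    rtol: float = 1e-12
    atol: float = 1e-14
    column_scaling: str = "norm"  # "norm" | "nominal" | "none"
    seed: int | None = None
    #: shrink the grid to the trajectory's domain of existence when a cheap
    #: state-only pre-integration detects finite-time blow-up (several of the
    #: benchmark models, e.g. dx/dt = p x^2, escape in finite time for
    #: generic positive parameter draws)
    adapt_horizon: bool = True
    state_bound: float = 1e6

    def __post_init__(self):
        if not self.t_end > self.t0:
            raise ValueError("t_end must exceed t0")
        if self.n_points < 2:
            raise ValueError("need at least 2 grid points")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("integration tolerances must be positive")
        if self.column_scaling not in ("norm", "nominal", "none"):
            raise ValueError(f"unknown column_scaling {self.column_scaling!r}")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t0, self.t_end, self.n_points)

    def input_functions(self, k: int):
        """Callables u_i(t), one per model input."""
        funcs = []
        for i in range(k):
            spec = self.input_signals[i] if i < len(self.input_signals) else ("constant", 1.0)
            kind = spec[0]
            if kind == "constant":
                v = float(spec[1])
                funcs.append(lambda t, v=v: v)
            elif kind == "piecewise":
                knots = np.asarray(spec[1], dtype=float)
                vals = np.asarray(spec[2], dtype=float)
                if len(vals) != len(knots) + 1:
                    raise ValueError("piecewise input needs len(values) == len(knots)+1")
                funcs.append(lambda t, knots=knots, vals=vals:
                             float(vals[np.searchsorted(knots, t, side="right")]))
            elif kind == "sines":
                amps = np.asarray(spec[1], dtype=float)
                freqs = np.asarray(spec[2], dtype=float)
                off = float(spec[3]) if len(spec) > 3 else 0.0
                funcs.append(lambda t, a=amps, w=freqs, o=off:
                             o + float(np.sum(a * np.sin(w * t))))
            else:
                raise ValueError(f"unknown input signal kind {kind!r}")
        return funcs

    def to_dict(self) -> dict:
        return {
            "t0": self.t0, "t_end": self.t_end, "n_points": self.n_points,
            "input_signals": [[list(part) if isinstance(part, (tuple, list))
                               else part for part in s]
                              for s in self.input_signals],
            "rtol": self.rtol, "atol": self.atol,
            "column_scaling": self.column_scaling, "seed": self.seed,
            "adapt_horizon": self.adapt_horizon, "state_bound": self.state_bound,
        }


# ---------------------------------------------------------------------------
# assembly of the augmented (state + sensitivity) system
# ---------------------------------------------------------------------------

@dataclass
class SensitivitySystem:
    """Compiled augmented ODE: states plus state sensitivities.

    The augmented vector is ``z = (x, vec(dx/dtheta))`` with dimension
    ``n + n*q``.  All callables take ``(x, theta, u)`` as flat numeric arrays.
    """

    model: OdeModel
    unknowns: tuple[sp.Symbol, ...]
    f_fun: object       # (x, theta, u) -> (n,)
    A_fun: object       # dF/dx  -> (n, n)
    B_fun: object       # dF/dtheta -> (n, q)
    h_fun: object       # (x, theta) -> (m,)
    C_fun: object       # dh/dx -> (m, n)
    D_fun: object       # dh/dtheta -> (m, q)

    @property
    def dim(self) -> int:
        n, q = self.model.n, len(self.unknowns)
        return n + n * q


def _lambdify(args, exprs):
    f = sp.lambdify(args, exprs, modules="numpy", cse=True)
    return f


def assemble_sensitivity_system(model: OdeModel) -> SensitivitySystem:
    """Build the coupled system for ``(x, dx/dtheta)`` of a validated,
    promoted model.

    The input-dependent blocks ``sum_i u_i (dF_i/dx dx/dtheta + dF_i/dtheta)``
    are included because the Jacobians are taken of the full right-hand side
    ``F = f0 + sum u_i f_i`` with the ``u_i`` kept as evaluation arguments.
    """
    n, q = model.n, len(model.unknowns)
    x = sp.Matrix(model.states)
    theta = sp.Matrix(model.unknowns) if q else sp.Matrix(sp.zeros(0, 1))
    u = list(model.inputs)
    const = {c: sp.Float(v) for c, v in model.constants}

    try:
        F = sp.Matrix(model.rhs()).xreplace(const)
        H = sp.Matrix(model.outputs).xreplace(const)
        A = F.jacobian(x)
        B = F.jacobian(theta) if q else sp.zeros(n, 0)
        C = H.jacobian(x)
        D = H.jacobian(theta) if q else sp.zeros(model.m, 0)
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"symbolic differentiation failed for model "
                         f"{model.name!r}: {exc}") from exc

    argx = [list(model.states), list(model.unknowns), u]
    return SensitivitySystem(
        model=model, unknowns=model.unknowns,
        f_fun=_lambdify(argx, F),
        A_fun=_lambdify(argx, A),
        B_fun=_lambdify(argx, B),
        h_fun=_lambdify(argx[:2], H),
        C_fun=_lambdify(argx[:2], C),
        D_fun=_lambdify(argx[:2], D),
    )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class SensitivityTrajectory:
    times: np.ndarray                 # (N+1,)
    outputs: np.ndarray               # (N+1, m)
    output_sensitivities: np.ndarray  # (N+1, m, q)
    unknowns: tuple[sp.Symbol, ...]


def _initial_state_exprs(model: OdeModel,
                         ic_values=None) -> sp.Matrix:
    """Initial-condition vector as expressions in the unknowns."""
    ics = model.initial_conditions if ic_values is None else tuple(ic_values)
    const = {c: sp.Float(v) for c, v in model.constants}
    return sp.Matrix([sp.sympify(e).xreplace(const) for e in ics])


def _existence_horizon(system, config, theta_num, x0, u_funcs) -> float:
    """Cheap state-only pre-integration; returns ``t_end``, shortened to 80%
    of the detected finite escape time if the state norm crosses
    ``config.state_bound`` before the end of the experiment window."""
    n = system.model.n

    def rhs(t, x):
        uv = np.array([f(t) for f in u_funcs], dtype=float)
        return np.asarray(system.f_fun(x, theta_num, uv), dtype=float).reshape(n)

    def blowup(t, x):
        return config.state_bound - float(np.max(np.abs(x)))
    blowup.terminal = True

    with np.errstate(over="ignore", invalid="ignore"):
        sol = scipy.integrate.solve_ivp(
            rhs, (config.t0, config.t_end), np.asarray(x0, dtype=float),
            method="RK45", rtol=1e-6, atol=1e-9, events=blowup)
    if sol.t_events and len(sol.t_events[0]):
        t_star = float(sol.t_events[0][0])
    elif not sol.success:
        t_star = float(sol.t[-1]) if sol.t.size else config.t0
    else:
        return config.t_end
    t_end = config.t0 + 0.8 * (t_star - config.t0)
    if not t_end > config.t0:
        raise IntegrationError(
            f"trajectory of model {system.model.name!r} leaves its domain of "
            f"existence immediately after t0 = {config.t0:g}", t_fail=config.t0)
    return t_end


def integrate_sensitivities(system: SensitivitySystem,
                            config: ExperimentConfig,
                            nominal: NominalAssignment,
                            ic_values=None) -> SensitivityTrajectory:
    """Integrate the augmented system and return ``dy/dtheta`` on the grid.

    ``ic_values`` optionally overrides the model's initial-condition
    expressions (one entry per state: number or expression in the unknowns).
    Initial state sensitivities are the Jacobian of the initial-condition
    vector with respect to the unknowns: an identity entry for a state whose
    initial value is its own promoted parameter, a chain-rule row for an
    initial value tied to parameters (e.g. ``x2(0) = p1/p3``), zero
    otherwise.
    """
    model = system.model
    n, q, m = model.n, len(system.unknowns), model.m
    theta_num = np.array([nominal.value_of(s) for s in system.unknowns], dtype=float)
    if not np.all(np.isfinite(theta_num)):
        raise ValueError("nominal assignment contains non-finite values")

    x0_expr = _initial_state_exprs(model, ic_values)
    subs = dict(zip(system.unknowns, theta_num))
    known = nominal.as_dict
    for s in x0_expr.free_symbols - set(system.unknowns):
        # known-but-generic symbols (e.g. a fixed nonzero initial value that
        # is not estimated) are constants for the sensitivity analysis
        if s in known:
            subs[s] = known[s]
        else:
            raise ValueError(
                f"initial conditions contain symbol without a nominal value: {s}")
    x0 = np.array([float(e.xreplace(subs)) for e in x0_expr], dtype=float)
    S0 = (np.array(x0_expr.jacobian(sp.Matrix(system.unknowns)).xreplace(subs),
                   dtype=float)
          if q else np.zeros((n, 0)))

    u_funcs = config.input_functions(model.k)

    t_end = config.t_end
    if config.adapt_horizon:
        t_end = _existence_horizon(system, config, theta_num, x0, u_funcs)

    def rhs(t, z):
        x = z[:n]
        Sx = z[n:].reshape(n, q)
        uv = np.array([f(t) for f in u_funcs], dtype=float)
        dx = np.asarray(system.f_fun(x, theta_num, uv), dtype=float).reshape(n)
        A = np.asarray(system.A_fun(x, theta_num, uv), dtype=float).reshape(n, n)
        B = np.asarray(system.B_fun(x, theta_num, uv), dtype=float).reshape(n, q)
        dS = A @ Sx + B
        return np.concatenate([dx, dS.reshape(-1)])

    def blowup(t, z):
        return config.state_bound - float(np.max(np.abs(z[:n])))
    blowup.terminal = True

    z0 = np.concatenate([x0, S0.reshape(-1)])
    times = np.linspace(config.t0, t_end, config.n_points)
    with np.errstate(over="ignore", invalid="ignore"):
        sol = scipy.integrate.solve_ivp(
            rhs, (config.t0, t_end), z0, method="LSODA",
            t_eval=times, rtol=config.rtol, atol=config.atol, events=blowup)
    if not sol.success or sol.y.shape[1] != len(times):
        t_fail = float(sol.t[-1]) if sol.t.size else config.t0
        if sol.t_events and len(sol.t_events[0]):
            t_fail = float(sol.t_events[0][0])
        raise IntegrationError(
            f"integration of model {model.name!r} failed at t = {t_fail:g}: "
            f"{sol.message}", t_fail=t_fail)

    ys = np.empty((len(times), m))
    dydth = np.empty((len(times), m, q))
    for j in range(len(times)):
        x = sol.y[:n, j]
        Sx = sol.y[n:, j].reshape(n, q)
        C = np.asarray(system.C_fun(x, theta_num), dtype=float).reshape(m, n)
        D = np.asarray(system.D_fun(x, theta_num), dtype=float).reshape(m, q)
        ys[j] = np.asarray(system.h_fun(x, theta_num), dtype=float).reshape(m)
        dydth[j] = C @ Sx + D
    return SensitivityTrajectory(times=times, outputs=ys,
                                 output_sensitivities=dydth,
                                 unknowns=system.unknowns)


# ---------------------------------------------------------------------------
# the stacked sensitivity matrix
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMatrix:
    """Stacked output sensitivities: row blocks ordered by time then output
    index, columns in unknown-vector order."""

    values: np.ndarray                    # (m*(N+1), q)
    labels: tuple[str, ...]               # column labels, unknown order
    times: np.ndarray
    n_outputs: int
    config: ExperimentConfig
    column_scale: np.ndarray | None = None  # applied scale factors, or None

    @property
    def shape(self):
        return self.values.shape


def build_sensitivity_matrix(traj: SensitivityTrajectory,
                             model: OdeModel,
                             config: ExperimentConfig,
                             nominal: NominalAssignment | None = None,
                             output_selection=None) -> SensitivityMatrix:
    """Stack the time-indexed sensitivities into the ``m(N+1) x q`` matrix.

    Scaling equalises magnitudes so that the SVD gap reflects structure
    rather than units.  Mode ``"norm"`` (the default) first clamps columns
    that are numerically zero — norm below ``1e-9`` times the largest column
    norm, i.e. at the level of integration error rather than signal — to
    exact zero, then applies a few rounds of iterative row/column norm
    equilibration (Ruiz scaling); diagonal scaling preserves the rank and
    the set of vanishing columns.  Mode ``"nominal"`` multiplies column
    ``j`` by the magnitude of unknown ``j``'s nominal value.
    """
    sel = tuple(range(model.m)) if output_selection is None else tuple(output_selection)
    q = len(traj.unknowns)
    N1 = len(traj.times)
    S = traj.output_sensitivities[:, sel, :].reshape(N1 * len(sel), q)
    scale = None
    if config.column_scaling == "norm":
        norms = np.linalg.norm(S, axis=0)
        ref = norms.max() if norms.size else 0.0
        if ref > 0:
            S = S.copy()
            S[:, norms <= 1e-9 * ref] = 0.0
            scale = np.ones_like(norms)
            for _ in range(3):
                rn = np.linalg.norm(S, axis=1)
                rmask = rn > 1e-9 * rn.max()
                rdiv = np.ones_like(rn)
                np.divide(1.0, np.sqrt(rn), out=rdiv, where=rmask)
                S = S * rdiv[:, np.newaxis]
                cn = np.linalg.norm(S, axis=0)
                cmask = cn > 1e-9 * max(cn.max(), 1e-300)
                cdiv = np.ones_like(cn)
                np.divide(1.0, np.sqrt(cn), out=cdiv, where=cmask)
                S = S * cdiv[np.newaxis, :]
                scale = scale * cdiv
    elif config.column_scaling == "nominal":
        if nominal is None:
            raise ValueError("column_scaling='nominal' requires the nominal assignment")
        scale = np.array([abs(nominal.value_of(s)) for s in traj.unknowns])
        scale[scale == 0.0] = 1.0
        S = S * scale[np.newaxis, :]
    if N1 < q:
        raise ValueError(
            f"time grid has {N1} points but there are {q} unknowns; "
            "S cannot reach full column rank")
    return SensitivityMatrix(values=S, labels=tuple(map(str, traj.unknowns)),
                             times=traj.times, n_outputs=len(sel),
                             config=config, column_scale=scale)


def sensitivity_matrix_to_csv(S: SensitivityMatrix, path: str) -> None:
    """CSV export: header = time, output, column labels."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "output"] + list(S.labels))
        r = 0
        for t in S.times:
            for j in range(S.n_outputs):
                w.writerow([repr(float(t)), j + 1] + [repr(v) for v in S.values[r]])
                r += 1
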