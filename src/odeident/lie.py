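"""Symbolic verification via Lie derivatives and the generating-series
Jacobi matrix.

For an uncontrolled model the output's generating-series coefficients are
``h`` and the successive Lie derivatives ``L_f0^r h`` along the drift,
evaluated at the initial state.  For a controlled model the output expands in
a Fliess series whose coefficients are iterated Lie derivatives
``L_{f_{j0}} ... L_{f_{jq}} h|_{x(0)}`` over words in the vector-field
indices ``{0, .., k}``.  Differentiating the coefficients with respect to a
selected set of unknowns gives the Jacobi matrix; full generic column rank is
sufficient for local structural identifiability of those unknowns, and a
nontrivial null-space names totally correlated parameter sets.  Each basis
vector of the null-space also yields a first-order linear PDE whose solutions
are the identifiable parameter combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import sympy as sp

__all__ = [
    "GeneratingSeries",
    "JacobiMatrix",
    "NullSpaceBasis",
    "DependencyPde",
    "VerificationResult",
    "SeriesBlowupError",
    "lie_derivative",
    "generating_series",
    "iter_words",
    "build_jacobi",
    "symbolic_rank",
    "null_space_basis",
    "emit_dependency_pde",
    "verify_candidates",
]

#: hard cap on sympy op-count of a single series coefficient
DEFAULT_SIZE_CAP = 200_000


class SeriesBlowupError(RuntimeError):
    """Series coefficient exceeded the expression-size cap; lower the order
    or restrict the analysed parameter set."""


def _tidy(e: sp.Expr) -> sp.Expr:
    """Canonical compact form: expanded for polynomials, a single cancelled
    fraction otherwise (expanding rational functions blows up the op count
    exponentially over successive Lie derivatives)."""
    e = sp.sympify(e)
    if e.is_polynomial():
        return sp.expand(e)
    return sp.cancel(sp.together(e))


def lie_derivative(expr: sp.Expr, field, states, tidy: bool = True) -> sp.Expr:
    """Directional derivative ``(d expr/dx) . field`` along a vector field.

    With ``tidy=False`` rational results are left unsimplified; iterated
    derivatives of rational fields are far cheaper on the raw expression
    tree, and the caller tidies once after substituting the initial state.
    """
    expr = sp.sympify(expr)
    out = sp.S.Zero
    for x, f in zip(states, field):
        out += sp.diff(expr, x) * f
    if out.is_polynomial():
        return sp.expand(out)
    return _tidy(out) if tidy else out


def iter_words(k: int, max_len: int):
    """Word ordering for Fliess-series rows: by word length; within each
    length the pure-drift power (0, .., 0) first, then the words containing
    at least one input index in lexicographic order.  For an uncontrolled
    model (k = 0) this is simply the successive drift powers."""
    yield ()
    for r in range(1, max_len + 1):
        yield (0,) * r
        if k > 0:
            for w in itertools.product(range(k + 1), repeat=r):
                if any(j > 0 for j in w):
                    yield w


@dataclass(frozen=True)
class GeneratingSeries:
    """Ordered series coefficients, one per (word, output) pair, as
    expressions in the states and parameters (not yet evaluated at x(0))."""

    entries: tuple[tuple[tuple[int, ...], int, sp.Expr], ...]
    max_word_length: int
    controlled: bool

    def coefficients(self):
        return tuple(e for _, _, e in self.entries)


def _rationalise(v):
    """Exact rational for a numeric value (floats would force the symbolic
    linear algebra into an inexact field with unreliable zero tests)."""
    v = sp.sympify(v)
    if v.is_number and not v.is_Rational:
        return sp.nsimplify(v, rational=True)
    return v


def _series_entries(model, words, size_cap=DEFAULT_SIZE_CAP,
                    skip_blowup: bool = False, blown: list | None = None):
    """Yield (word, output index, coefficient expression) lazily.

    The coefficient of word ``(j0, .., jq)`` is computed by applying the
    fields innermost-first: ``L_{f_j0} (... (L_{f_jq} h))``.  A coefficient
    exceeding ``size_cap`` operations raises; with ``skip_blowup`` the
    offending output is instead dropped from all longer words and the event
    recorded in *blown* (when a list is supplied).
    """
    const = {c: _rationalise(v) for c, v in model.constants}
    fields = [tuple(sp.sympify(e).xreplace(const) for e in model.drift)]
    for f in model.input_fields:
        fields.append(tuple(sp.sympify(e).xreplace(const) for e in f))
    outputs = [sp.sympify(h).xreplace(const) for h in model.outputs]
    cache: dict[tuple[tuple[int, ...], int], sp.Expr | None] = {}

    def coeff(word, i):
        key = (word, i)
        if key in cache:
            return cache[key]
        if not word:
            e = outputs[i]
        else:
            inner = coeff(word[1:], i)
            if inner is None:
                cache[key] = None
                return None
            e = lie_derivative(inner, fields[word[0]], model.states, tidy=False)
        if sp.count_ops(e) > size_cap:
            if skip_blowup:
                cache[key] = None
                if blown is not None:
                    blown.append((word, i))
                return None
            raise SeriesBlowupError(
                f"series coefficient for word {word} of output {i + 1} exceeds "
                f"{size_cap} operations; lower the maximum order")
        cache[key] = e
        return e

    for w in words:
        for i in range(model.m):
            e = coeff(w, i)
            if e is not None:
                yield w, i, e


def generating_series(model, max_order: int,
                      size_cap: int = DEFAULT_SIZE_CAP) -> GeneratingSeries:
    """Series coefficients up to word length ``max_order``.

    Uncontrolled models get the ``max_order + 1`` drift coefficients
    ``{h, L h, ..., L^max h}`` per output; controlled models additionally get
    every word over the field indices up to that length.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    words = list(iter_words(model.k, max_order))
    entries = tuple(_series_entries(model, words, size_cap))
    return GeneratingSeries(entries=entries, max_word_length=max_order,
                            controlled=model.k > 0)


# ---------------------------------------------------------------------------
# Jacobi matrix of the series coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JacobiMatrix:
    """Partial derivatives of the series coefficients with respect to the
    selected unknowns, after substituting the scenario's initial conditions
    for the states (the evaluation "in the point x(0)")."""

    M: sp.Matrix
    selected: tuple[sp.Symbol, ...]
    rows: tuple[tuple[tuple[int, ...], int], ...]  # (word, output index) per row

    @property
    def shape(self):
        return self.M.shape


def build_jacobi(series: GeneratingSeries, theta_sel,
                 ic_substitutions) -> JacobiMatrix:
    """Substitute the scenario initial conditions into the coefficients, then
    differentiate each with respect to each selected unknown.

    ``ic_substitutions`` maps every state symbol to its initial value
    (number, zero, IC-parameter symbol, or expression in the parameters);
    substitution happens *before* differentiation, which is precisely how
    initial-condition-specific unidentifiability manifests.
    """
    theta_sel = tuple(sp.sympify(t) for t in theta_sel)
    if not theta_sel:
        raise ValueError("theta_sel must be nonempty")
    subs = {sp.sympify(k): _rationalise(v)
            for k, v in dict(ic_substitutions).items()}
    rows = []
    data = []
    for word, i, e in series.entries:
        e0 = _tidy(sp.sympify(e).xreplace(subs))
        data.append([_tidy(sp.diff(e0, t)) for t in theta_sel])
        rows.append((word, i))
    return JacobiMatrix(M=sp.Matrix(data), selected=theta_sel, rows=tuple(rows))


def _iszero(e) -> bool:
    # cancel/together decides exactly for rational expressions; the full
    # simplify fallback is reserved for small non-rational entries
    e = sp.cancel(sp.together(e))
    if e.is_zero:
        return True
    if e.is_number:
        return False
    if sp.count_ops(e) <= 400 and not e.is_rational_function(*e.free_symbols):
        return bool(sp.simplify(e) == 0)
    return False


def _as_domain_matrix(M: sp.Matrix):
    """Exact sparse representation over the fraction field QQ(symbols);
    None when the entries are not rational functions."""
    from sympy.polys.matrices import DomainMatrix

    try:
        dm = DomainMatrix.from_Matrix(M, extension=True)
        return dm.to_field()
    except Exception:
        return None


def symbolic_rank(J: JacobiMatrix | sp.Matrix) -> int:
    """Exact generic rank over the field of rational functions of the free
    symbols (rank at a generic point, not at special parameter values)."""
    M = J.M if isinstance(J, JacobiMatrix) else sp.Matrix(J)
    if M.rows == 0 or M.cols == 0:
        return 0
    dm = _as_domain_matrix(M)
    if dm is not None:
        return dm.rank()
    return M.rank(iszerofunc=_iszero, simplify=False)


@dataclass(frozen=True)
class NullSpaceBasis:
    """Generic null-space basis of a Jacobi matrix, each vector normalised so
    its last nonzero entry is 1."""

    vectors: tuple[tuple[sp.Expr, ...], ...]
    selected: tuple[sp.Symbol, ...]

    def __len__(self):
        return len(self.vectors)


def _normalise(vec) -> tuple[sp.Expr, ...]:
    entries = [sp.cancel(sp.together(e)) for e in vec]
    pivot = None
    for e in reversed(entries):
        if not _iszero(e):
            pivot = e
            break
    if pivot is None:
        return tuple(entries)
    return tuple(sp.cancel(e / pivot) for e in entries)


def null_space_basis(J: JacobiMatrix) -> NullSpaceBasis:
    """Basis of the generic null-space; empty when the matrix has full
    column rank.  Each basis vector symbolically annihilates the matrix."""
    M = J.M
    if M.rows == 0:
        vecs = [sp.eye(len(J.selected)).col(i) for i in range(len(J.selected))]
    else:
        dm = _as_domain_matrix(M)
        if dm is not None:
            # normalise inside the fraction field: domain division keeps
            # entries canonical without sympy-level cancel on large
            # polynomials
            ns = dm.nullspace()
            K = ns.domain
            out = []
            for r in ns.rep.to_ddm().to_list():
                piv = next((x for x in reversed(r) if x), None)
                if piv is None:
                    out.append(tuple(sp.S.Zero for _ in r))
                else:
                    out.append(tuple(K.to_sympy(x / piv) for x in r))
            return NullSpaceBasis(vectors=tuple(out), selected=J.selected)
        vecs = M.nullspace(iszerofunc=_iszero, simplify=False)
    return NullSpaceBasis(vectors=tuple(_normalise(v) for v in vecs),
                          selected=J.selected)


# ---------------------------------------------------------------------------
# the correlation PDE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DependencyPde:
    """First-order linear PDE ``sum_j c_j d(phi)/d(theta_j) = 0`` describing
    the linear dependence encoded by one null-space basis vector; its
    solutions phi are the identifiable parameter combinations."""

    coefficients: tuple[sp.Expr, ...]
    selected: tuple[sp.Symbol, ...]

    def __str__(self):
        terms = [f"({sp.sstr(c)})*d(phi)/d({t})"
                 for c, t in zip(self.coefficients, self.selected)
                 if not _iszero(c)]
        return " + ".join(terms) + " = 0"

    def residual(self, candidate: sp.Expr) -> sp.Expr:
        """Substitute a candidate first integral phi; zero iff it solves the
        PDE."""
        phi = sp.sympify(candidate)
        r = sum(c * sp.diff(phi, t) for c, t in zip(self.coefficients, self.selected))
        return sp.simplify(sp.cancel(sp.together(r)))


def emit_dependency_pde(basis_vector, theta_sel) -> DependencyPde:
    return DependencyPde(coefficients=tuple(sp.sympify(c) for c in basis_vector),
                         selected=tuple(sp.sympify(t) for t in theta_sel))


# ---------------------------------------------------------------------------
# staged verification of numeric candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VerificationResult:
    """Outcome of the staged symbolic check of a candidate set.

    ``verdict`` is "identifiable" (the null-space was destroyed as rows were
    added), "unidentifiable" (a stable nontrivial null-space persisted up to
    the row cap — a bounded-evidence verdict) or "inconclusive" (symbolic
    blow-up before a stable answer)."""

    verdict: str
    basis: NullSpaceBasis
    rank: int
    n_rows: int
    selected: tuple[sp.Symbol, ...]
    per_unknown: tuple[tuple[str, str], ...]  # (unknown, identifiable|unidentifiable)

    @property
    def unidentifiable_set(self) -> tuple[str, ...]:
        return tuple(u for u, v in self.per_unknown if v == "unidentifiable")


def _basis_key(basis: NullSpaceBasis):
    return frozenset(tuple(sp.srepr(sp.cancel(e)) for e in v) for v in basis.vectors)


def verify_candidates(model, theta_unid, ic_substitutions,
                      stable_rounds: int = 2,
                      row_cap: int | None = None,
                      size_cap: int = DEFAULT_SIZE_CAP,
                      bind_inputs=None) -> VerificationResult:
    """Staged null-space check of the Jacobi matrix restricted to the
    numerically suggested set ``theta_unid``.

    The Jacobi matrix grows stage by stage, one word per stage (i.e. one
    Lie-derivative order, across all outputs), keeping only informative rows
    — those whose restricted derivatives are not all identically zero.
    After each stage that contributed rows, the generic null-space is
    recomputed: an empty null-space ends the procedure with verdict
    "identifiable"; a basis unchanged (as a set of normalised vectors) for
    ``stable_rounds`` consecutive contributing stages, or exhausting the row
    cap / word supply with a nontrivial basis, yields "unidentifiable"
    together with the basis — a bounded-evidence verdict.

    ``bind_inputs`` (mapping input symbol -> value) folds the input fields
    into the drift at a fixed stimulus, so the series describes exactly that
    experiment; without it, controlled models are expanded over Fliess words
    (length-bounded, since their number grows as ``(k+1)^length``).
    Per-output expression blow-ups drop only that output's deeper words; if
    no stable answer is reached before the supply runs dry the verdict is
    "inconclusive", never silent.
    """
    theta_sel = tuple(sp.sympify(t) for t in theta_unid)
    if not theta_sel:
        raise ValueError("theta_unid must be nonempty")
    if row_cap is None:
        row_cap = 3 * len(theta_sel) + 4
    subs = {sp.sympify(k): _rationalise(v)
            for k, v in dict(ic_substitutions).items()}

    import dataclasses

    work = model
    if bind_inputs is not None and model.k:
        u_vals = {sp.sympify(k): _rationalise(v)
                  for k, v in dict(bind_inputs).items()}
        work = dataclasses.replace(model, drift=model.rhs(u_vals),
                                   inputs=(), input_fields=())

    # states pinned at zero that are flow-invariant can be substituted into
    # the dynamics: the series then lives on the invariant manifold, which
    # both shrinks the expressions and makes severed information flow (e.g. a
    # parameter cancelling from the reduced equations) explicit
    from .model_core import invariant_zero_states

    zero_pinned = {x for x, v in subs.items()
                   if x in set(work.states) and v == 0}
    inv = invariant_zero_states(work, zero_pinned)
    if inv:
        red = {x: sp.S.Zero for x in inv}
        idx = {x: i for i, x in enumerate(work.states)}
        for x in inv:
            ic = work.initial_conditions[idx[x]]
            if ic.is_Symbol and ic in set(work.ic_params) and ic not in theta_sel:
                red[ic] = sp.S.Zero
        work = dataclasses.replace(
            work,
            drift=tuple(_tidy(sp.sympify(e).xreplace(red)) for e in work.drift),
            input_fields=tuple(tuple(_tidy(sp.sympify(e).xreplace(red)) for e in f)
                               for f in work.input_fields),
            outputs=tuple(_tidy(sp.sympify(e).xreplace(red)) for e in work.outputs),
        )
    # a selected unknown that appears nowhere in the (reduced, bound)
    # dynamics, outputs or initial values has an identically zero column:
    # it contributes a unit null vector outright and is excluded from the
    # staged computation
    used: set = set()
    for e in (work.drift + tuple(itertools.chain.from_iterable(work.input_fields))
              + work.outputs + tuple(subs.values())):
        used |= sp.sympify(e).free_symbols
    present = tuple(t for t in theta_sel if t in used)
    absent = tuple(t for t in theta_sel if t not in used)

    rows: list[list[sp.Expr]] = []
    row_ids: list[tuple[tuple[int, ...], int]] = []
    part_verdict = "identifiable"
    part_basis: tuple = ()
    blown: list = []
    if present:
        part_verdict, part_basis, rows, row_ids, blown = _staged_nullspace(
            work, present, subs, stable_rounds, row_cap, size_cap)

    # compose the basis over the full selection: unit vectors for absent
    # unknowns plus the present-subset null vectors padded with zeros
    pos = {t: j for j, t in enumerate(theta_sel)}
    vectors = []
    for t in absent:
        v = [sp.S.Zero] * len(theta_sel)
        v[pos[t]] = sp.S.One
        vectors.append(tuple(v))
    for pv in part_basis:
        v = [sp.S.Zero] * len(theta_sel)
        for t, e in zip(present, pv):
            v[pos[t]] = e
        vectors.append(tuple(v))
    basis = NullSpaceBasis(vectors=tuple(vectors), selected=theta_sel)

    if not vectors:
        per = tuple((str(t), "identifiable") for t in theta_sel)
        return VerificationResult(
            verdict="identifiable", basis=basis, rank=len(theta_sel),
            n_rows=len(rows), selected=theta_sel, per_unknown=per)
    per = tuple((str(t), "unidentifiable" if any(
        not _iszero(v[j]) for v in basis.vectors) else "identifiable")
        for j, t in enumerate(theta_sel))
    verdict = "inconclusive" if part_verdict == "inconclusive" else "unidentifiable"
    return VerificationResult(
        verdict=verdict, basis=basis,
        rank=len(theta_sel) - len(basis), n_rows=len(rows),
        selected=theta_sel, per_unknown=per)


def _staged_nullspace(work, theta_sel, subs, stable_rounds, row_cap, size_cap):
    """Inner staged loop of :func:`verify_candidates` over unknowns that
    actually occur in the model; returns (verdict, basis vectors, rows,
    row ids, blown)."""
    max_len = row_cap + 2 if work.k == 0 else min(row_cap + 2, 8)
    blown: list = []
    entry_gen = _series_entries(work, iter_words(work.k, max_len), size_cap,
                                skip_blowup=True, blown=blown)

    rows: list[list[sp.Expr]] = []
    row_ids: list[tuple[tuple[int, ...], int]] = []
    prev_key = None
    stable = 0
    basis = None
    exhausted = False
    done = False
    current_word = None
    stage_rows = 0

    def evaluate():
        nonlocal basis, prev_key, stable
        J = JacobiMatrix(M=sp.Matrix(rows), selected=tuple(theta_sel),
                         rows=tuple(row_ids))
        basis = null_space_basis(J)
        if len(basis) == 0:
            return "identifiable"
        key = _basis_key(basis)
        stable = stable + 1 if key == prev_key else 1
        prev_key = key
        return "stable" if stable >= stable_rounds else None

    while not done:
        try:
            word, i, e = next(entry_gen)
        except StopIteration:
            exhausted = True
            break
        if word != current_word:
            if stage_rows:
                outcome = evaluate()
                if outcome == "identifiable":
                    return "identifiable", (), rows, row_ids, blown
                if outcome == "stable":
                    done = True
                    break
            current_word = word
            stage_rows = 0
        e0 = _tidy(sp.sympify(e).xreplace(subs))
        if not (e0.free_symbols & set(theta_sel)):
            continue
        row = [_tidy(sp.diff(e0, t)) for t in theta_sel]
        if all(_iszero(r) for r in row):
            continue
        rows.append(row)
        row_ids.append((word, i))
        stage_rows += 1
        if len(rows) >= row_cap:
            break

    if stage_rows and not done:
        outcome = evaluate()
        if outcome == "identifiable":
            return "identifiable", (), rows, row_ids, blown

    if basis is None:
        # informative rows never appeared although the unknowns occur in the
        # model: treat all columns as zero (bounded evidence)
        vecs = tuple(tuple(sp.eye(len(theta_sel)).col(i))
                     for i in range(len(theta_sel)))
        verdict = "inconclusive" if blown else "unidentifiable"
        return verdict, vecs, rows, row_ids, blown
    verdict = "unidentifiable"
    if exhausted and blown and stable < stable_rounds and rows:
        verdict = "inconclusive"
    return verdict, tuple(basis.vectors), rows, row_ids, blown
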