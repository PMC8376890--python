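"""Initial-condition patterns and the search for problematic / reinstating
initial-value sets.

A "problematic" set of initial conditions is a (typically zero-valued) set on
which an otherwise identifiable model loses local structural identifiability
— a thin set in initial-condition space.  Conversely, switching selected zero
initial values to generic nonzero ones can reinstate the identifiability of
an unidentifiable scenario.  Both directions are explored by classifying
explicit zero/nonzero patterns with the numeric signature, repeating each
classification over several generic draws to guard against non-generic
nominal points, and confirming positives symbolically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .model_core import NominalAssignment, OdeModel
from .sensitivity import (ExperimentConfig, IntegrationError,
                          assemble_sensitivity_system, build_sensitivity_matrix,
                          integrate_sensitivities)
from .signature import (DEFAULT_COMPONENT_THRESHOLD, DEFAULT_MIN_DECADES,
                        compute_signature)
from . import lie

__all__ = [
    "IcPattern",
    "ClassifyResult",
    "SearchResult",
    "draw_loguniform",
    "detect_invariant_zero_states",
    "resolve_pattern",
    "classify_pattern",
    "search_reinstating_sets",
    "search_problematic_sets",
]

#: generic nonzero draws: log-uniform on [0.1, 10], positive
LOGUNIFORM_RANGE = (0.1, 10.0)


def draw_loguniform(rng: np.random.Generator, size=None):
    lo, hi = np.log10(LOGUNIFORM_RANGE)
    return 10.0 ** rng.uniform(lo, hi, size=size)


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IcPattern:
    """Zero/nonzero assignment over the initial conditions.

    One entry per state, in state order.  Entry kinds:
    ``("zero",)``, ``("generic",)`` (fresh positive draw per evaluation),
    ``("fixed", value)``, ``("unknown", symbol)`` (an unknown initial
    condition, estimated alongside the parameters) and ``("expr", expr)``
    (an initial value tied to the parameters, e.g. ``p1/p3``).
    """

    entries: tuple[tuple, ...]
    label: str = ""

    def __post_init__(self):
        for e in self.entries:
            if e[0] not in ("zero", "generic", "fixed", "unknown", "expr"):
                raise ValueError(f"unknown pattern entry kind {e[0]!r}")

    @staticmethod
    def from_map(model: OdeModel, mapping, label: str = "") -> "IcPattern":
        """Build a pattern from ``{state name: entry}``; states not named
        default to the model's own initial condition (zero stays zero,
        an unknown marker stays unknown, numbers become fixed)."""
        entries = []
        for x, ic in zip(model.states, model.initial_conditions):
            key = str(x)
            if key in mapping:
                e = mapping[key]
                entries.append((e,) if isinstance(e, str) else tuple(e))
            elif ic.is_Symbol and ic not in set(model.params):
                entries.append(("unknown", ic))
            elif ic.is_number:
                if ic == 0:
                    entries.append(("zero",))
                else:
                    entries.append(("fixed", float(ic)))
            else:
                entries.append(("expr", ic))
        return IcPattern(entries=tuple(entries), label=label)

    def zero_states(self, model: OdeModel) -> tuple[sp.Symbol, ...]:
        return tuple(x for x, e in zip(model.states, self.entries)
                     if e[0] == "zero" or (e[0] == "fixed" and float(e[1]) == 0.0))

    def with_changes(self, model: OdeModel, to_generic) -> "IcPattern":
        """Switch the named states' entries to generic-nonzero."""
        names = {str(s) for s in to_generic}
        entries = []
        for x, e in zip(model.states, self.entries):
            entries.append(("generic",) if str(x) in names else e)
        lab = (self.label + " + " if self.label else "") + \
            ", ".join(f"{n}(0)!=0" for n in sorted(names))
        return IcPattern(entries=tuple(entries), label=lab)

    def describe(self, model: OdeModel) -> str:
        if self.label:
            return self.label
        bits = []
        for x, e in zip(model.states, self.entries):
            if e[0] == "zero":
                bits.append(f"{x}(0)=0")
        return ", ".join(bits) or "all nonzero"


# ---------------------------------------------------------------------------
# invariant-zero states
# ---------------------------------------------------------------------------

def detect_invariant_zero_states(model: OdeModel,
                                 pattern: IcPattern) -> set[sp.Symbol]:
    """Largest set Z of zero-initial-value states of *pattern* such that
    substituting ``x_Z = 0`` makes every ``dx_j/dt``, ``j in Z``, identically
    zero (fixed point of symbolic substitution).  Those states then stay at
    zero for all time, regardless of the input signals."""
    from .model_core import invariant_zero_states

    return invariant_zero_states(model, pattern.zero_states(model))


# ---------------------------------------------------------------------------
# resolving a pattern into initial-value expressions + nominal values
# ---------------------------------------------------------------------------

def resolve_pattern(model: OdeModel, pattern: IcPattern,
                    rng: np.random.Generator,
                    base_values: dict | None = None):
    """Turn a pattern into per-state initial-value expressions plus a full
    nominal assignment for the unknowns.

    States whose initial condition is a promoted parameter keep the symbol in
    the expression slot (so the sensitivity column with respect to that
    initial value is computed) and receive their pattern value — possibly
    exactly zero — as the nominal value of the symbol.  All unknowns without
    a pinned value get a fresh generic positive draw.
    """
    if len(pattern.entries) != model.n:
        raise ValueError("pattern does not cover every state exactly once")
    values: dict[sp.Symbol, float] = dict(base_values or {})
    ic_exprs: list[sp.Expr] = []
    promoted = set(model.ic_params)
    for x, ic, e in zip(model.states, model.initial_conditions, pattern.entries):
        kind = e[0]
        sym = ic if (ic.is_Symbol and ic in promoted) else None
        if kind == "zero":
            val = 0.0
        elif kind == "generic":
            val = float(draw_loguniform(rng))
        elif kind == "fixed":
            val = float(e[1])
        elif kind == "unknown":
            sym = sp.sympify(e[1])
            val = values.get(sym)
        else:  # expr
            ic_exprs.append(sp.sympify(e[1]))
            continue
        if sym is not None:
            ic_exprs.append(sym)
            if val is not None:
                values[sym] = val
        else:
            ic_exprs.append(sp.Float(val if val is not None else 0.0))
    for s in model.unknowns:
        if s not in values:
            values[s] = float(draw_loguniform(rng))
    # any unknown-marker symbols in the expressions that are not part of the
    # unknown vector (e.g. a known-but-generic x1(0)) also need values
    for expr in ic_exprs:
        for s in sp.sympify(expr).free_symbols - set(model.unknowns):
            if s not in values:
                values[s] = float(draw_loguniform(rng))
    return tuple(ic_exprs), values


def _ic_substitutions(model: OdeModel, pattern: IcPattern) -> dict:
    """State -> symbolic initial value, for the symbolic verification step:
    zeros substituted exactly, generic/unknown values kept symbolic."""
    subs = {}
    promoted = set(model.ic_params)
    for x, ic, e in zip(model.states, model.initial_conditions, pattern.entries):
        kind = e[0]
        if kind == "zero":
            subs[x] = sp.S.Zero
        elif kind == "fixed":
            subs[x] = sp.Float(float(e[1])) if float(e[1]) != 0 else sp.S.Zero
        elif kind == "unknown":
            subs[x] = sp.sympify(e[1])
        elif kind == "expr":
            subs[x] = sp.sympify(e[1])
        else:  # generic: keep symbolic, as a fresh nonzero symbol
            subs[x] = ic if (ic.is_Symbol and ic in promoted) or (
                ic.is_Symbol and ic not in set(model.params)) else sp.Symbol(f"{x}_0")
    return subs


# ---------------------------------------------------------------------------
# classification of a single pattern
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifyResult:
    pattern: IcPattern
    verdict: str                      # identifiable | unidentifiable | ambiguous | untestable
    candidates: tuple[str, ...]
    n_draws: int
    seed: int | None = None
    cause: str | None = None          # for untestable patterns
    signatures: tuple = ()

    def representative_signature(self):
        """The signature shown in reports: the first draw agreeing with the
        majority (gap present?, candidate set) outcome across the draws."""
        if not self.signatures:
            return None
        from collections import Counter

        keys = [(s.identifiable, frozenset(s.candidates)) for s in self.signatures]
        majority = Counter(keys).most_common(1)[0][0]
        for sig, key in zip(self.signatures, keys):
            if key == majority:
                return sig
        return self.signatures[0]


def classify_pattern(model: OdeModel, pattern: IcPattern,
                     config: ExperimentConfig | None = None,
                     seed: int = 0, n_draws: int = 3,
                     min_decades: float = DEFAULT_MIN_DECADES,
                     component_threshold: float = DEFAULT_COMPONENT_THRESHOLD,
                     base_values: dict | None = None,
                     output_selection=None,
                     system=None) -> ClassifyResult:
    """Numeric verdict for one initial-condition pattern.

    The signature is computed ``n_draws`` times with fresh generic draws for
    every free slot; the verdict (gap present? plus candidate set) must be
    unanimous, otherwise the pattern is flagged "ambiguous" for symbolic
    follow-up.  "identifiable" means no gap in any draw.
    """
    config = config or ExperimentConfig()
    if system is None:
        system = assemble_sensitivity_system(model)
    rng = np.random.default_rng(seed)
    verdicts = []
    sigs = []
    for _ in range(n_draws):
        ic_exprs, values = resolve_pattern(model, pattern, rng, base_values)
        nominal = NominalAssignment.from_dict(values, provenance="seeded-random",
                                              seed=seed)
        try:
            traj = integrate_sensitivities(system, config, nominal, ic_exprs)
        except IntegrationError as exc:
            return ClassifyResult(pattern=pattern, verdict="untestable",
                                  candidates=(), n_draws=n_draws, seed=seed,
                                  cause=str(exc))
        S = build_sensitivity_matrix(traj, model, config, nominal,
                                     output_selection)
        sig = compute_signature(S, min_decades, component_threshold)
        verdicts.append((sig.identifiable, frozenset(sig.candidates)))
        sigs.append(sig)
    unanimous = len(set(verdicts)) == 1
    if not unanimous:
        return ClassifyResult(pattern=pattern, verdict="ambiguous",
                              candidates=tuple(sorted(set().union(
                                  *(v[1] for v in verdicts)))),
                              n_draws=n_draws, seed=seed, signatures=tuple(sigs))
    identifiable, cand = verdicts[0]
    return ClassifyResult(
        pattern=pattern,
        verdict="identifiable" if identifiable else "unidentifiable",
        candidates=tuple(sorted(cand, key=list(map(str, model.unknowns)).index)),
        n_draws=n_draws, seed=seed, signatures=tuple(sigs))


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    mode: str                                  # "reinstate" | "problematic"
    tested: list = field(default_factory=list)  # (change/zero set, ClassifyResult, confirmed)
    reinstating: list = field(default_factory=list)   # minimal change-sets (tuples of state names)
    problematic: list = field(default_factory=list)   # zero-sets (tuples of state names)
    budget_used: int = 0
    incomplete: bool = False
    seed: int | None = None

    def to_table(self):
        """Rows mirroring the published search tables: pattern, verdict,
        candidate set, symbolic confirmation."""
        rows = []
        for names, res, confirmed in self.tested:
            rows.append({
                "states": ", ".join(names),
                "n_states": len(names),
                "verdict": res.verdict,
                "theta_unid": ", ".join(res.candidates),
                "confirmed_symbolically": confirmed,
            })
        return rows


def search_reinstating_sets(model: OdeModel, base_pattern: IcPattern,
                            config: ExperimentConfig | None = None,
                            max_changes: int = 3, budget: int = 200,
                            seed: int = 0, n_draws: int = 3,
                            **classify_kw) -> SearchResult:
    """Breadth-first search for minimal zero-to-nonzero changes that
    reinstate identifiability of an unidentifiable base scenario.

    Change-sets of size 1, 2, ... up to ``max_changes`` are classified;
    supersets of an already-found reinstating set are skipped (minimality).
    """
    zero_names = [str(x) for x in base_pattern.zero_states(model)]
    result = SearchResult(mode="reinstate", seed=seed)
    ss = np.random.SeedSequence(seed)
    classify_kw.setdefault("system", assemble_sensitivity_system(model))
    for size in range(1, max_changes + 1):
        for combo in itertools.combinations(zero_names, size):
            if any(set(m).issubset(combo) for m in result.reinstating):
                continue
            if result.budget_used >= budget:
                result.incomplete = True
                return result
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            pat = base_pattern.with_changes(model, combo)
            res = classify_pattern(model, pat, config, seed=sub_seed,
                                   n_draws=n_draws, **classify_kw)
            result.budget_used += 1
            result.tested.append((combo, res, None))
            if res.verdict == "identifiable":
                result.reinstating.append(combo)
    return result


def search_problematic_sets(model: OdeModel,
                            config: ExperimentConfig | None = None,
                            max_zeros: int = 3, budget: int = 200,
                            seed: int = 0, n_draws: int = 3,
                            base_pattern: IcPattern | None = None,
                            confirm_symbolically: bool = True,
                            **classify_kw) -> SearchResult:
    """Search zero-valued initial-condition sets that destroy the
    identifiability of a generically identifiable model.

    Enumerates zero-sets of size 1 .. ``max_zeros`` (not exhaustive beyond
    that size, by construction).  Every numerically unidentifiable pattern is
    re-confirmed symbolically before being reported as problematic; numeric
    positives the symbolic step cannot confirm are kept as "suspected" in the
    tested list but stay out of the problematic list.
    """
    if base_pattern is None:
        base_pattern = IcPattern.from_map(
            model, {str(x): ("generic",) for x in model.states},
            label="all generic")
    state_names = [str(x) for x in model.states]
    result = SearchResult(mode="problematic", seed=seed)
    ss = np.random.SeedSequence(seed)
    classify_kw.setdefault("system", assemble_sensitivity_system(model))
    for size in range(1, max_zeros + 1):
        for combo in itertools.combinations(state_names, size):
            if result.budget_used >= budget:
                result.incomplete = True
                return result
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            entries = []
            for x, e in zip(model.states, base_pattern.entries):
                entries.append(("zero",) if str(x) in combo else e)
            pat = IcPattern(entries=tuple(entries),
                            label="=0: " + ", ".join(combo))
            res = classify_pattern(model, pat, config, seed=sub_seed,
                                   n_draws=n_draws, **classify_kw)
            result.budget_used += 1
            confirmed = None
            # ambiguous (non-unanimous) patterns are flagged for symbolic
            # confirmation rather than discarded
            if res.verdict in ("unidentifiable", "ambiguous") and res.candidates:
                if confirm_symbolically:
                    confirmed = _confirm(model, pat, res.candidates)
                    if confirmed:
                        result.problematic.append(combo)
                elif res.verdict == "unidentifiable":
                    result.problematic.append(combo)
            result.tested.append((combo, res, confirmed))
    return result


def _confirm(model: OdeModel, pattern: IcPattern, candidates) -> bool:
    """Symbolic re-check of a numeric positive via the staged null-space
    test restricted to the flagged unknowns."""
    label_map = {str(s): s for s in model.unknowns}
    theta = [label_map[c] for c in candidates if c in label_map]
    if not theta:
        return False
    subs = _ic_substitutions(model, pattern)
    try:
        ver = lie.verify_candidates(model, theta, subs)
    except lie.SeriesBlowupError:
        return False
    return ver.verdict == "unidentifiable"
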