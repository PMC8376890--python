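"""Directed state-influence graph and its strongly connected components.

The graph is a structural diagnostic: node ``x_b`` points to ``x_a`` when the
equation of ``x_a`` depends on ``x_b`` (the Jacobian entry of the full
right-hand side is not identically zero), after substituting the states that
the chosen initial-condition pattern keeps at zero for all time.  Zero-valued
invariant states sever edges and can split the graph into several strongly
connected components, visualising why information cannot flow from the
measured outputs into part of the model.
"""

from __future__ import annotations

import networkx as nx
import sympy as sp

from .ic_search import IcPattern, detect_invariant_zero_states
from .model_core import OdeModel

__all__ = ["build_graph", "strongly_connected_components", "to_dot"]


def build_graph(model: OdeModel, pattern: IcPattern | None = None) -> nx.DiGraph:
    """Influence graph with edge ``x_b -> x_a`` iff the Jacobian entry
    ``d(dx_a/dt)/d(x_b)`` is not identically zero after substituting the
    invariant-zero states implied by *pattern* (no substitution when
    *pattern* is None).

    The substitution is applied to the Jacobian entry, i.e. the coupling is
    evaluated on the invariant manifold: a state frozen at zero keeps the
    edges of its own (linearised) subsystem but loses the couplings that are
    proportional to its value.  Edges are decided by symbolic non-vanishing
    at generic parameters, not by numeric magnitude.  Output-measured states
    are marked with the node attribute ``measured=True``.
    """
    subs: dict = {}
    if pattern is not None:
        zero = detect_invariant_zero_states(model, pattern)
        subs = {x: sp.S.Zero for x in zero}
        idx = {x: i for i, x in enumerate(model.states)}
        for x in zero:
            ic = model.initial_conditions[idx[x]]
            if ic.is_Symbol and ic in set(model.ic_params):
                subs[ic] = sp.S.Zero

    rhs = model.rhs()
    measured = set()
    for h in model.outputs:
        measured |= sp.sympify(h).free_symbols & set(model.states)

    g = nx.DiGraph()
    for x in model.states:
        g.add_node(str(x), measured=x in measured)
    for a, expr in zip(model.states, rhs):
        for b in model.states:
            entry = sp.cancel(sp.together(sp.diff(expr, b))).xreplace(subs)
            if sp.simplify(entry) != 0:
                g.add_edge(str(b), str(a))
    return g


def strongly_connected_components(graph: nx.DiGraph,
                                  state_order=None) -> list[frozenset]:
    """SCC partition in deterministic order (by the smallest member's
    position in *state_order*, else lexicographic)."""
    comps = [frozenset(c) for c in nx.strongly_connected_components(graph)]
    if state_order is not None:
        pos = {str(s): i for i, s in enumerate(state_order)}
        keyf = lambda c: min(pos.get(n, len(pos)) for n in c)
    else:
        keyf = lambda c: min(c)
    return sorted(comps, key=keyf)


def to_dot(graph: nx.DiGraph) -> str:
    """Plain DOT serialisation (measured states drawn as double circles)."""
    lines = ["digraph influence {"]
    for n, data in sorted(graph.nodes(data=True)):
        shape = "doublecircle" if data.get("measured") else "circle"
        lines.append(f'  "{n}" [shape={shape}];')
    for a, b in sorted(graph.edges()):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
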