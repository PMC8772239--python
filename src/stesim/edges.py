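"""Edge specificity weights and the inherited/own IC decomposition.

Each parent → child edge gets a weight

    omega(i, j) = sum of IC over Desc(t_j) / sum of IC over Desc(t_i)

where the descendant sets include the term itself, so 0 < omega <= 1 (the
numerator term set is a subset of the denominator's).  A term's IC then
splits into the part inherited from its direct parents,

    IC_inherited(t_j) = sum over parents t_i of omega(i, j) * IC(t_i),

and its own residual IC_own(t_j) = IC(t_j) - IC_inherited(t_j), clamped at
zero (multi-parent terms can over-inherit; clamps are flagged).  The IC of
an ancestor-closed term set is the sum of own-IC over the set, which counts
shared semantics once instead of once per term.

Rounding note: all arithmetic is full precision.  The 3-decimal half-up
trace formatter exists to reproduce the hand-calculation style of the
worked example, where each step's own-IC is rounded before accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx

from .ic import ICTable
from .ontology import OntologyError, OntologyGraph, ancestor_closure

__all__ = [
    "EdgeWeightTable",
    "OwnICTable",
    "edge_weights",
    "own_ic",
    "set_ic",
    "set_ic_trace",
    "round_half_up",
]


@dataclass
class EdgeWeightTable:
    """omega per (parent, child) edge, derived from one ICTable."""

    weights: dict[tuple[str, str], float]
    ic_model: str

    def __getitem__(self, edge: tuple[str, str]) -> float:
        return self.weights[edge]

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class OwnICTable:
    """Inherited/own split of per-term IC over a closed term set."""

    own: dict[str, float]
    inherited: dict[str, float]
    clamped: set[str] = field(default_factory=set)

    def total(self) -> float:
        return sum(self.own.values())


def edge_weights(graph: OntologyGraph, ic: ICTable) -> EdgeWeightTable:
    """Specificity weight of every edge: ratio of the child's to the
    parent's self-inclusive descendant IC mass.

    An all-zero parent subtree (denominator 0) yields omega = 1.
    """
    missing = graph.terms - set(ic.values)
    if missing:
        raise ValueError(f"ICTable missing {len(missing)} graph terms, e.g. {sorted(missing)[0]}")
    # subtree IC mass in reverse topological order: S(t) would double-count
    # shared descendants if summed over children, so sum the set explicitly
    mass: dict[str, float] = {}
    for term in graph.dag.nodes:
        mass[term] = ic[term] + sum(ic[d] for d in graph.descendants(term))
    weights: dict[tuple[str, str], float] = {}
    for parent, child in graph.dag.edges:
        denom = mass[parent]
        weights[(parent, child)] = mass[child] / denom if denom > 0 else 1.0
    return EdgeWeightTable(weights=weights, ic_model=ic.model)


def _check_closed(termset: set[str], graph: OntologyGraph) -> None:
    for term in termset:
        if term not in graph:
            raise OntologyError(f"term {term} is not in the graph")
        missing = graph.parents(term) - termset
        if missing:
            raise OntologyError(
                f"term set is not ancestor-closed: {term} lacks parent {sorted(missing)[0]}"
            )


def _topo_subset(termset: set[str], graph: OntologyGraph) -> list[str]:
    # lexicographic tie-break makes trace step order deterministic
    sub = graph.dag.subgraph(termset)
    return list(nx.lexicographical_topological_sort(sub))


def own_ic(
    termset: set[str],
    graph: OntologyGraph,
    ic: ICTable,
    weights: EdgeWeightTable,
) -> OwnICTable:
    """Inherited and own IC for every term of an ancestor-closed set.

    Terms are processed in topological order; the closure precondition
    guarantees every direct parent is present.  Negative pre-clamp own
    values are clamped to 0 and recorded in ``clamped``.
    """
    _check_closed(termset, graph)
    own: dict[str, float] = {}
    inherited: dict[str, float] = {}
    clamped: set[str] = set()
    for term in _topo_subset(termset, graph):
        inh = sum(weights[(p, term)] * ic[p] for p in graph.parents(term))
        raw = ic[term] - inh
        if raw < 0:
            clamped.add(term)
            raw = 0.0
        inherited[term] = inh
        own[term] = raw
    return OwnICTable(own=own, inherited=inherited, clamped=clamped)


def set_ic(
    termset: set[str],
    graph: OntologyGraph,
    ic: ICTable,
    weights: EdgeWeightTable,
) -> float:
    """IC of a term set: sum of own-IC over its ancestor closure.

    The closure is applied internally, so any nonempty set is accepted.
    The empty set is an error ({root} legitimately scores 0.0).
    """
    if not termset:
        raise ValueError("set_ic of the empty set is undefined (did you mean {root}?)")
    closed = ancestor_closure(set(termset), graph)
    return own_ic(closed, graph, ic, weights).total()


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal half-up rounding (0.0005 -> 0.001), immune to float noise."""
    quant = Decimal(1).scaleb(-decimals)
    # pre-round at 10 decimals so binary representation error cannot flip
    # a half-way case
    return float(Decimal(repr(round(x, 10))).quantize(quant, rounding=ROUND_HALF_UP))


def set_ic_trace(
    termset: set[str],
    graph: OntologyGraph,
    ic: ICTable,
    weights: EdgeWeightTable,
    decimals: int = 3,
) -> list[dict]:
    """Step-by-step accumulation trace of :func:`set_ic`.

    One row per term in topological order with keys ``step``, ``term``,
    ``ic``, ``own`` (half-up rounded to ``decimals``) and ``cumulative``
    (running sum of the rounded own values, itself rounded).  This mirrors
    the hand-calculation convention in which each step is rounded before
    being added.
    """
    if not termset:
        raise ValueError("cannot trace the empty set")
    closed = ancestor_closure(set(termset), graph)
    table = own_ic(closed, graph, ic, weights)
    rows: list[dict] = []
    cumulative = 0.0
    for step, term in enumerate(_topo_subset(closed, graph), start=1):
        own_r = round_half_up(table.own[term], decimals)
        cumulative = round_half_up(cumulative + own_r, decimals)
        rows.append({
            "step": step,
            "term": term,
            "ic": ic[term],
            "own": own_r,
            "cumulative": cumulative,
        })
    return rows
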