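"""Brute-force reference implementations used only by the tests.

Everything here is deliberately naive — exhaustive path enumeration and
explicit per-term formulas — and shares no code path with the package
internals it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from stesim import EdgeWeightTable, ICTable, OntologyGraph
from stesim.ic import compute_depths


def enumerate_root_paths(graph: OntologyGraph, term: str) -> list[list[str]]:
    if term == graph.root:
        return [[graph.root]]
    return list(nx.all_simple_paths(graph.dag, graph.root, term))


def brute_depth(graph: OntologyGraph, term: str) -> int:
    """Longest root→term path length by exhaustive enumeration."""
    return max(len(p) for p in enumerate_root_paths(graph, term))


def brute_ancestors(graph: OntologyGraph, term: str) -> set[str]:
    """Ancestors = every node on any root→term path, excluding term."""
    nodes = set()
    for path in enumerate_root_paths(graph, term):
        nodes.update(path)
    nodes.discard(term)
    return nodes


def brute_descendants(graph: OntologyGraph, term: str) -> set[str]:
    """Descendants = nodes with some root path passing through term."""
    return {t for t in graph.terms
            if t != term and any(term in p for p in enumerate_root_paths(graph, t))}


def brute_closure(terms: set[str], graph: OntologyGraph) -> set[str]:
    """Fixed-point closure by repeated direct-parent addition."""
    closed = set(terms)
    changed = True
    while changed:
        changed = False
        for t in list(closed):
            for p in graph.parents(t):
                if p not in closed:
                    closed.add(p)
                    changed = True
    return closed


def brute_set_ic(
    terms: set[str],
    graph: OntologyGraph,
    ic: ICTable,
    weights: EdgeWeightTable,
) -> float:
    """Own-IC sum by explicit parent enumeration, no ordering at all."""
    total = 0.0
    for t in brute_closure(terms, graph):
        inherited = sum(weights[(p, t)] * ic[p] for p in graph.parents(t))
        total += max(0.0, ic[t] - inherited)
    return total


def random_topological_order(graph: OntologyGraph, termset: set[str], rng) -> list[str]:
    """A uniformly perturbed valid topological order of the closed set."""
    remaining = set(termset)
    done: set[str] = set()
    order = []
    while remaining:
        ready = sorted(t for t in remaining if (graph.parents(t) & termset) <= done)
        pick = ready[rng.integers(len(ready))]
        order.append(pick)
        done.add(pick)
        remaining.remove(pick)
    return order


def set_ic_in_order(
    order: list[str],
    graph: OntologyGraph,
    ic: ICTable,
    weights: EdgeWeightTable,
) -> float:
    """Accumulate own-IC following an externally supplied topological order."""
    total = 0.0
    for t in order:
        inherited = sum(weights[(p, t)] * ic[p] for p in graph.parents(t))
        total += max(0.0, ic[t] - inherited)
    return total


def random_dag(rng, n_max: int = 12) -> OntologyGraph:
    """Random single-rooted DAG with <= n_max nodes for oracle tests."""
    n = int(rng.integers(2, n_max + 1))
    ids = [f"GO:{9000000 + i}" for i in range(n)]
    dag = nx.DiGraph()
    dag.add_nodes_from(ids)
    for j in range(1, n):
        # at least one parent among earlier nodes keeps it rooted and acyclic
        parents = [i for i in range(j) if rng.random() < 0.4] or [int(rng.integers(j))]
        for i in parents:
            dag.add_edge(ids[i], ids[j], relation="is_a")
    graph = OntologyGraph(namespace="BP", dag=dag, root=ids[0])
    graph.validate()
    return graph


def random_ic(graph: OntologyGraph, rng) -> ICTable:
    """Random term IC with IC(root) = 0, roughly increasing with depth."""
    depth = compute_depths(graph)
    values = {
        t: 0.0 if t == graph.root else float(rng.uniform(0, 1)) * depth[t]
        for t in graph.terms
    }
    top = max(values.values()) or 1.0
    return ICTable(model="random", values={t: v / top for t, v in values.items()},
                   normalized=True, depth=depth, N=len(graph))


def brute_auc(scores: list[float], labels: list[int]) -> float:
    """Pair-counting AUC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))
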