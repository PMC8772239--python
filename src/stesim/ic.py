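"""Per-term information content (IC) models.

Three models are provided.  The structural model at the package's core
scores a term by combining three topological signals: its depth (longest
root-to-term path), the summed depths of its ancestors, and its number of
descendants relative to the ontology size,

    IC(t) = log(depth(t)) * (log(sum of ancestor depths) + 1)
                          * (1 - log(|Desc(t)| + 1) / log(N + 1))

with natural logarithms, depth(root) = 1, ancestors excluding t, and
descendants excluding t (the +1 gives leaves the maximal specificity
factor).  The comparison models are the classical corpus model
IC = -log p(t) over annotation frequencies under the true-path closure, and
the Sánchez structural model from leaf/subsumer counts.

All models give IC(root) = 0; with ``normalize=True`` values are divided by
the maximum so they lie in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationMap, OntologyGraph, ancestor_closure

__all__ = [
    "ICTable",
    "compute_depths",
    "ste_ic",
    "corpus_ic",
    "sanchez_ic",
    "ic_distribution",
]


@dataclass
class ICTable:
    """Per-term IC values under a named model, with topology indices."""

    model: str
    values: dict[str, float]
    normalized: bool
    depth: dict[str, int]
    N: int
    #: terms whose IC was imputed (e.g. never-annotated terms under the
    #: corpus model, assigned the maximum observed IC)
    flagged: set[str] = field(default_factory=set)

    def __getitem__(self, term: str) -> float:
        return self.values[term]

    def __contains__(self, term: str) -> bool:
        return term in self.values

    def max_ic(self) -> float:
        return max(self.values.values())


def compute_depths(graph: OntologyGraph) -> dict[str, int]:
    """Longest-path depth of every term: number of nodes on the longest
    root → term path, so depth(root) = 1."""
    depth: dict[str, int] = {}
    for node in graph.topological_order():
        parents = graph.parents(node)
        depth[node] = 1 if not parents else 1 + max(depth[p] for p in parents)
    return depth


def _finish(model: str, raw: dict[str, float], normalize: bool,
            depth: dict[str, int], n: int, flagged: set[str] | None = None) -> ICTable:
    values = dict(raw)
    if normalize:
        top = max(values.values())
        if top > 0:
            values = {t: v / top for t, v in values.items()}
    return ICTable(model=model, values=values, normalized=normalize,
                   depth=depth, N=n, flagged=flagged or set())


def ste_ic(graph: OntologyGraph, normalize: bool = True) -> ICTable:
    """Structural IC from depth, ancestor depths and descendant counts."""
    n = len(graph)
    if n == 0:
        raise ValueError("cannot compute IC on an empty graph")
    depth = compute_depths(graph)
    log_n1 = math.log(n + 1)
    raw: dict[str, float] = {}
    for term in graph.dag.nodes:
        d = depth[term]
        if d == 1:  # root: log(1) = 0 annihilates the product
            raw[term] = 0.0
            continue
        anc_depth_sum = sum(depth[a] for a in graph.ancestors(term))
        n_desc = len(graph.descendants(term))
        spec = 1.0 - math.log(n_desc + 1) / log_n1
        ic = math.log(d) * (math.log(anc_depth_sum) + 1.0) * spec
        assert ic >= 0.0, f"negative IC for {term}"
        raw[term] = ic
    return _finish("ste", raw, normalize, depth, n)


def corpus_ic(annotations: AnnotationMap, graph: OntologyGraph,
              normalize: bool = True) -> ICTable:
    """Annotation-frequency IC: -log p(t), with p(t) the fraction of genes
    whose closed annotation set contains t.

    Terms annotating no gene have undefined IC; they are assigned the
    maximum observed IC and listed in ``flagged``.
    """
    if len(annotations) == 0:
        raise ValueError("corpus IC requires a non-empty annotation map")
    counts: dict[str, int] = {t: 0 for t in graph.dag.nodes}
    total = 0
    for gene in annotations.genes:
        direct = annotations.direct_terms(gene)
        if not direct:
            continue
        total += 1
        for term in ancestor_closure(direct, graph):
            counts[term] += 1
    if total == 0:
        raise ValueError("no gene carries any annotation")
    raw: dict[str, float] = {}
    flagged: set[str] = set()
    for term, c in counts.items():
        if c > 0:
            raw[term] = -math.log(c / total)
        else:
            flagged.add(term)
    top = max(raw.values()) if raw else 0.0
    for term in flagged:
        raw[term] = top
    depth = compute_depths(graph)
    return _finish("corpus", raw, normalize, depth, len(graph), flagged)


def sanchez_ic(graph: OntologyGraph, normalize: bool = True) -> ICTable:
    """Sánchez structural IC from leaf and subsumer counts.

    leaves(t) are the leaf descendants of t (a leaf's leaves are itself);
    subsumers(t) are the ancestors of t including t.
    """
    n = len(graph)
    leaves = {t for t in graph.dag.nodes if graph.dag.out_degree(t) == 0}
    max_leaves = len(leaves)
    raw: dict[str, float] = {}
    for term in graph.dag.nodes:
        if term in leaves:
            n_leaves = 1
        else:
            n_leaves = len(graph.descendants(term) & leaves)
        n_subsumers = len(graph.ancestors(term)) + 1
        raw[term] = -math.log((n_leaves / n_subsumers + 1.0) / (max_leaves + 1.0))
    depth = compute_depths(graph)
    return _finish("sanchez", raw, normalize, depth, n)


def ic_distribution(table: ICTable, bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of term counts over IC bins on [0, 1].

    Returns ``(bin_edges, counts)``; the sum of counts equals the number of
    terms.  Requires a normalized table.
    """
    if not table.normalized:
        raise ValueError("ic_distribution expects a normalized ICTable")
    values = np.fromiter(table.values.values(), dtype=float)
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return edges, counts
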