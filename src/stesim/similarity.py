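"""Gene–gene functional similarity measures.

The central measure scores two genes by the ratio of the set-IC of the
intersection of their annotation sets to the set-IC of their union,

    sim(G1, G2) = IC(T_G1 ∩ T_G2) / IC(T_G1 ∪ T_G2),

where T_G is the ancestor closure of the gene's direct annotations and the
set-IC is the own-IC sum from :mod:`stesim.edges`.  Intersections and
unions of closed sets are themselves closed, so both arguments are valid
set-IC inputs.  Four standard group-wise/pairwise baselines are provided:
term-overlap Jaccard (simUI), binary-vector cosine (VSM), IC-weighted
Jaccard (simGIC), and Resnik term similarity aggregated by best-match
average (BMA).

A gene with an empty direct annotation set has no defined similarity; the
scalar functions return NaN for such pairs (never 0, which is a meaningful
score) and :func:`pairwise_matrix` flags them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edges import EdgeWeightTable, set_ic
from .ic import ICTable
from .ontology import AnnotationMap, OntologyGraph, ancestor_closure

__all__ = [
    "SimilarityResult",
    "sim_ste",
    "sim_resnik_bma",
    "sim_ui",
    "sim_vsm",
    "sim_gic",
    "pairwise_matrix",
    "METHODS",
]


def _closed(gene: str, annotations: AnnotationMap, graph: OntologyGraph) -> set[str] | None:
    direct = annotations.direct_terms(gene)
    if not direct:
        return None
    return ancestor_closure(direct, graph)


def sim_ste(
    gene_a: str,
    gene_b: str,
    annotations: AnnotationMap,
    graph: OntologyGraph,
    ic: ICTable,
    weights: EdgeWeightTable,
) -> float:
    """Own-IC overlap ratio of the two closed annotation sets.

    Returns NaN if either gene is unannotated.  Two sets meeting only at
    the root score 0 (the root carries no own IC).  Degenerate all-zero-IC
    unions score 1 when the sets are identical, NaN otherwise.
    """
    ta, tb = _closed(gene_a, annotations, graph), _closed(gene_b, annotations, graph)
    if ta is None or tb is None:
        return math.nan
    union = ta | tb
    denom = set_ic(union, graph, ic, weights)
    if denom == 0.0:
        return 1.0 if ta == tb else math.nan
    return set_ic(ta & tb, graph, ic, weights) / denom


def sim_ui(
    gene_a: str,
    gene_b: str,
    annotations: AnnotationMap,
    graph: OntologyGraph,
) -> float:
    """Jaccard index of the ancestor-closed annotation sets."""
    ta, tb = _closed(gene_a, annotations, graph), _closed(gene_b, annotations, graph)
    if ta is None or tb is None:
        return math.nan
    return len(ta & tb) / len(ta | tb)


def sim_vsm(
    gene_a: str,
    gene_b: str,
    annotations: AnnotationMap,
    graph: OntologyGraph,
) -> float:
    """Cosine of binary term-presence vectors over the closed sets.

    For binary one-hot vectors the cosine reduces to
    |A ∩ B| / sqrt(|A| * |B|); closed sets always share the root, so the
    score is strictly positive.
    """
    ta, tb = _closed(gene_a, annotations, graph), _closed(gene_b, annotations, graph)
    if ta is None or tb is None:
        return math.nan
    return len(ta & tb) / math.sqrt(len(ta) * len(tb))


def sim_gic(
    gene_a: str,
    gene_b: str,
    annotations: AnnotationMap,
    graph: OntologyGraph,
    ic: ICTable,
) -> float:
    """IC-weighted Jaccard: sum of plain IC over the intersection of the
    closed sets divided by the sum over their union."""
    ta, tb = _closed(gene_a, annotations, graph), _closed(gene_b, annotations, graph)
    if ta is None or tb is None:
        return math.nan
    denom = sum(ic[t] for t in ta | tb)
    if denom == 0.0:
        return 1.0 if ta == tb else math.nan
    return sum(ic[t] for t in ta & tb) / denom


def _resnik_term(t1: str, t2: str, graph: OntologyGraph, ic: ICTable) -> float:
    common = (graph.ancestors(t1) | {t1}) & (graph.ancestors(t2) | {t2})
    # multiple "lowest" common ancestors can coexist in a DAG; take the
    # most informative one
    return max(ic[t] for t in common)


def sim_resnik_bma(
    gene_a: str,
    gene_b: str,
    annotations: AnnotationMap,
    graph: OntologyGraph,
    ic: ICTable,
) -> float:
    """Resnik term similarity (IC of the most informative common ancestor)
    over the direct annotation sets, aggregated by best-match average:
    half the mean of row maxima plus half the mean of column maxima.

    Expects a normalized (corpus) ICTable so scores lie in [0, 1].
    """
    sa, sb = annotations.direct_terms(gene_a), annotations.direct_terms(gene_b)
    if not sa or not sb:
        return math.nan
    la, lb = sorted(sa), sorted(sb)
    m = np.array([[_resnik_term(a, b, graph, ic) for b in lb] for a in la])
    return 0.5 * (m.max(axis=1).mean() + m.max(axis=0).mean())


#: method name -> (function, which extra arguments it takes)
METHODS = {
    "ste": (sim_ste, ("ic", "weights")),
    "resnik": (sim_resnik_bma, ("ic",)),
    "simui": (sim_ui, ()),
    "vsm": (sim_vsm, ()),
    "simgic": (sim_gic, ("ic",)),
}


@dataclass
class SimilarityResult:
    """All-vs-all similarity matrix with method provenance.

    ``matrix[i, j]`` is the score between ``genes[i]`` and ``genes[j]``;
    NaN marks undefined pairs (unannotated genes).
    """

    method: str
    genes: list[str]
    matrix: np.ndarray
    config: dict = field(default_factory=dict)

    def score(self, gene_a: str, gene_b: str) -> float:
        i, j = self.genes.index(gene_a), self.genes.index(gene_b)
        return float(self.matrix[i, j])

    def to_long(self) -> pd.DataFrame:
        """Long-format table: gene_a, gene_b, score, defined (upper triangle
        including the diagonal)."""
        rows = []
        for i, j in itertools.combinations_with_replacement(range(len(self.genes)), 2):
            s = float(self.matrix[i, j])
            rows.append((self.genes[i], self.genes[j], s, not math.isnan(s)))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "defined"])


def pairwise_matrix(
    genes: list[str],
    method: str,
    annotations: AnnotationMap,
    graph: OntologyGraph,
    ic: ICTable | None = None,
    weights: EdgeWeightTable | None = None,
    config: dict | None = None,
) -> SimilarityResult:
    """Symmetric all-vs-all similarity matrix for the named method.

    Undefined pairs (unannotated genes) are NaN, never 0.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    fn, needs = METHODS[method]
    extra = []
    for name in needs:
        value = {"ic": ic, "weights": weights}[name]
        if value is None:
            raise ValueError(f"method {method!r} requires {name}")
        extra.append(value)
    n = len(genes)
    m = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            s = fn(genes[i], genes[j], annotations, graph, *extra)
            m[i, j] = m[j, i] = s
    return SimilarityResult(
        method=method,
        genes=list(genes),
        matrix=m,
        config=dict(config or {}, namespace=graph.namespace),
    )
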