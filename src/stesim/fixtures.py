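"""Reference fixture and synthetic data generators.

``worked_example`` builds the 8-term DAG used throughout the documentation
and tests, with published term-IC and edge-weight values injected directly
(bypassing the IC and weight models) so the inherited/own decomposition and
set-IC accumulation can be checked by hand.

The synthetic generators produce GO-like ontologies (rooted DAGs whose
depth distribution peaks at intermediate levels, as the real GO's does) and
GOA-like annotation maps (direct annotations biased toward specific terms,
with a tunable fraction of electronically inferred IEA evidence), so every
part of the package is testable without downloading anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .edges import EdgeWeightTable
from .ic import ICTable, compute_depths
from .ontology import AnnotationMap, OntologyGraph

__all__ = [
    "WorkedExample",
    "SyntheticOntologySpec",
    "worked_example",
    "generate_ontology",
    "generate_annotations",
]

# the 8-term reference DAG: labels t_1..t_8, edges parent -> child
_WE_EDGES = [
    (1, 2), (1, 3), (2, 4), (3, 4), (3, 5),
    (4, 6), (4, 7), (5, 7), (6, 8), (7, 8),
]
_WE_IC = [0.0, 0.01, 0.02, 0.04, 0.05, 0.07, 0.09, 0.18]
_WE_OMEGA = [0.85, 0.98, 0.97, 0.84, 0.71, 0.65, 0.71, 0.72, 0.67, 0.84]


def _we_id(i: int) -> str:
    return f"GO:000000{i}"


@dataclass
class WorkedExample:
    """The 8-term reference DAG with injected IC and edge weights."""

    graph: OntologyGraph
    ic: ICTable
    omega: EdgeWeightTable
    #: human label (t_1..t_8) -> term id
    labels: dict[str, str]

    def term(self, label: str) -> str:
        """Term id for a label such as ``"t_4"`` (or plain ``"4"``)."""
        return self.labels[label if label.startswith("t_") else f"t_{label}"]


def worked_example() -> WorkedExample:
    """Build the reference fixture, ready for the own-IC decomposition.

    IC and omega are given inputs here, not outputs of the IC/weight
    models: the published weights were derived on the full ontology, not on
    this excerpt, so recomputing them in-DAG would not reproduce them.
    """
    dag = nx.DiGraph()
    for i in range(1, 9):
        dag.add_node(_we_id(i))
    for (i, j) in _WE_EDGES:
        # one part_of edge exercises the relation-agnostic downstream path
        rel = "part_of" if (i, j) == (4, 7) else "is_a"
        dag.add_edge(_we_id(i), _we_id(j), relation=rel)
    graph = OntologyGraph(
        namespace="BP",
        dag=dag,
        root=_we_id(1),
        names={_we_id(i): f"t_{i}" for i in range(1, 9)},
    )
    graph.validate()
    ic = ICTable(
        model="injected",
        values={_we_id(i): v for i, v in enumerate(_WE_IC, start=1)},
        normalized=True,
        depth=compute_depths(graph),
        N=8,
    )
    omega = EdgeWeightTable(
        weights={(_we_id(i), _we_id(j)): w for (i, j), w in zip(_WE_EDGES, _WE_OMEGA)},
        ic_model="injected",
    )
    labels = {f"t_{i}": _we_id(i) for i in range(1, 9)}
    return WorkedExample(graph=graph, ic=ic, omega=omega, labels=labels)


@dataclass
class SyntheticOntologySpec:
    """Parameters of the random-ontology generator.

    ``n_terms`` total terms; ``max_depth`` deepest level (root level = 1);
    ``branching`` caps the growth factor between consecutive levels;
    ``multi_parent_prob`` is the chance a non-root term gains a second
    parent from a strictly shallower level.
    """

    n_terms: int = 500
    max_depth: int = 8
    branching: float = 3.0
    multi_parent_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.max_depth < 2:
            raise ValueError("max_depth must be >= 2")
        if self.max_depth > self.n_terms:
            raise ValueError("max_depth cannot exceed n_terms")
        if self.branching <= 0:
            raise ValueError("branching must be positive")
        if not 0.0 <= self.multi_parent_prob <= 1.0:
            raise ValueError("multi_parent_prob must lie in [0, 1]")


def _level_sizes(spec: SyntheticOntologySpec) -> list[int]:
    """Unimodal interior-peaked level sizes summing to n_terms.

    Binomial-shaped target across levels 2..max_depth (most real GO terms
    sit at intermediate depths), with growth between consecutive levels
    capped at the branching factor.
    """
    from scipy.stats import binom

    depths = spec.max_depth - 1  # levels 2..max_depth
    budget = spec.n_terms - 1
    if depths == 1:
        return [1, budget]
    pmf = binom.pmf(np.arange(depths), depths - 1, 0.5)
    sizes = np.maximum(1, np.round(pmf / pmf.sum() * budget).astype(int))
    # enforce the branching cap level by level (previous level incl. root)
    prev = 1
    for k in range(depths):
        cap = max(1, int(np.ceil(prev * spec.branching)))
        sizes[k] = min(sizes[k], cap)
        prev = sizes[k]
    # settle the exact budget on the interior levels
    diff = budget - int(sizes.sum())
    order = np.argsort(-pmf)
    i = 0
    while diff != 0:
        k = order[i % depths]
        if diff > 0:
            sizes[k] += 1
            diff -= 1
        elif sizes[k] > 1:
            sizes[k] -= 1
            diff += 1
        i += 1
    return [1] + list(sizes)


def generate_ontology(spec: SyntheticOntologySpec | None = None, **kwargs) -> OntologyGraph:
    """Random rooted DAG passing all OntologyGraph invariants.

    Reproducible per seed.  Keyword arguments override spec fields, so
    ``generate_ontology(n_terms=50, seed=3)`` works without building a spec.
    """
    if spec is None:
        spec = SyntheticOntologySpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a spec or keyword arguments, not both")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = _level_sizes(spec)

    dag = nx.DiGraph()
    term_ids = [f"GO:{1000000 + i:07d}" for i in range(spec.n_terms)]
    levels: list[list[str]] = []
    idx = 0
    for size in sizes:
        levels.append(term_ids[idx: idx + size])
        idx += size
    for level_terms in levels:
        dag.add_nodes_from(level_terms)
    root = levels[0][0]

    for d in range(1, len(levels)):
        shallower = [t for lvl in levels[:d] for t in lvl]
        for term in levels[d]:
            primary = levels[d - 1][rng.integers(len(levels[d - 1]))]
            dag.add_edge(primary, term, relation="is_a")
            if rng.random() < spec.multi_parent_prob:
                extra = shallower[rng.integers(len(shallower))]
                if extra != primary and not dag.has_edge(extra, term):
                    rel = "part_of" if rng.random() < 0.2 else "is_a"
                    dag.add_edge(extra, term, relation=rel)

    graph = OntologyGraph(namespace="BP", dag=dag, root=root)
    graph.validate()
    return graph


def generate_annotations(
    graph: OntologyGraph,
    n_genes: int = 100,
    mean_terms: float = 4.0,
    iea_fraction: float = 0.4,
    seed: int = 0,
) -> AnnotationMap:
    """GOA-like random annotation map.

    Each gene draws Poisson(mean_terms) + 1 distinct direct terms with
    probability proportional to depth squared (real annotation is
    concentrated on specific terms); each annotation is evidence IEA with
    probability ``iea_fraction``, otherwise EXP.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    terms = sorted(graph.terms)
    depth = compute_depths(graph)
    w = np.array([depth[t] ** 2 for t in terms], dtype=float)
    p = w / w.sum()
    amap = AnnotationMap(namespace=graph.namespace)
    for g in range(n_genes):
        gene = f"G{g:04d}"
        k = min(int(rng.poisson(mean_terms)) + 1, len(terms))
        chosen = rng.choice(len(terms), size=k, replace=False, p=p)
        for t_idx in chosen:
            evidence = "IEA" if rng.random() < iea_fraction else "EXP"
            amap.add(gene, terms[t_idx], evidence)
    return amap
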