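"""Gene Ontology structure and annotation input.

Reads one namespace of the GO (BP, CC or MF) from an OBO flat file into a
rooted DAG, and gene annotations from a GAF 2.x file into a gene → term-set
map.  Only the ``is_a`` and ``part_of`` relations carry semantics here; all
other relationship types are counted and ignored.  Ancestor closure
implements the true-path rule: a gene annotated to a term is implicitly
annotated to every ancestor of that term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet

__all__ = [
    "OntologyGraph",
    "AnnotationMap",
    "OntologyError",
    "parse_obo",
    "parse_gaf",
    "ancestor_closure",
    "write_obo",
    "write_gaf",
]

#: namespace tag -> OBO namespace name and GAF aspect letter
NAMESPACES = {
    "BP": ("biological_process", "P"),
    "CC": ("cellular_component", "C"),
    "MF": ("molecular_function", "F"),
}

KEPT_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Malformed input or a violated structural invariant."""


def _norm_namespace(namespace: str) -> str:
    ns = namespace.strip().upper().rstrip("+-")
    long_to_tag = {v[0].upper(): k for k, v in NAMESPACES.items()}
    ns = long_to_tag.get(ns, ns)
    if ns not in NAMESPACES:
        raise OntologyError(f"unknown namespace {namespace!r}; expected BP, CC or MF")
    return ns


@dataclass
class OntologyGraph:
    """One namespace of the ontology as a rooted DAG.

    ``dag`` is a :class:`networkx.DiGraph` directed parent → child, each edge
    carrying a ``relation`` attribute (``is_a`` or ``part_of``).  ``root`` is
    the unique term with no parents.  ``alt_ids`` maps secondary identifiers
    to their primary term.
    """

    namespace: str
    dag: nx.DiGraph
    root: str
    alt_ids: dict[str, str] = field(default_factory=dict)
    n_ignored_relations: int = 0
    names: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.dag.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.dag

    def __len__(self) -> int:
        return self.dag.number_of_nodes()

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id (primary ids pass through)."""
        return self.alt_ids.get(term, term)

    def parents(self, term: str) -> set[str]:
        return set(self.dag.predecessors(term))

    def children(self, term: str) -> set[str]:
        return set(self.dag.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable child → parent, excluding ``term`` itself."""
        return nx.ancestors(self.dag, term)

    def descendants(self, term: str) -> set[str]:
        """All terms reachable parent → child, excluding ``term`` itself."""
        return nx.descendants(self.dag, term)

    def edges(self) -> set[tuple[str, str, str]]:
        return {(p, c, d["relation"]) for p, c, d in self.dag.edges(data=True)}

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.dag))

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`OntologyError`."""
        if not nx.is_directed_acyclic_graph(self.dag):
            cycle = nx.find_cycle(self.dag)
            raise OntologyError(f"ontology graph contains a cycle through {cycle[0][0]}")
        roots = [n for n in self.dag if self.dag.in_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root in namespace {self.namespace}, found {sorted(roots)}"
            )
        if roots[0] != self.root:
            raise OntologyError(f"declared root {self.root} is not the parentless term {roots[0]}")
        unreachable = set(self.dag) - nx.descendants(self.dag, self.root) - {self.root}
        if unreachable:
            raise OntologyError(
                f"{len(unreachable)} terms cannot reach the root, e.g. {sorted(unreachable)[0]}"
            )


def _precheck_obo(path: str) -> None:
    # obonet's own errors lack positions; do a cheap structural scan first so
    # malformed stanza lines are reported with a line number.
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("!"):
                continue
            if stripped.startswith("["):
                if not stripped.endswith("]"):
                    raise OntologyError(f"{path}:{lineno}: malformed stanza header {stripped!r}")
                in_term = stripped == "[Term]"
                continue
            if in_term and ":" not in stripped:
                raise OntologyError(f"{path}:{lineno}: malformed tag line {stripped!r}")


def parse_obo(path: str, namespace: str) -> OntologyGraph:
    """Read one namespace of an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Obsolete terms are excluded (obonet already drops them), only ``is_a`` and
    ``part_of`` edges are kept (others counted in ``n_ignored_relations``),
    cross-namespace edges are discarded, and ``alt_id`` identifiers are
    recorded as aliases of their primary term.
    """
    ns = _norm_namespace(namespace)
    ns_long = NAMESPACES[ns][0]
    _precheck_obo(path)
    try:
        multi = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - obonet error text varies
        raise OntologyError(f"failed to parse OBO file {path}: {exc}") from exc

    dag = nx.DiGraph()
    alt_ids: dict[str, str] = {}
    names: dict[str, str] = {}
    keep = {n for n, d in multi.nodes(data=True) if d.get("namespace") == ns_long}
    for node in keep:
        dag.add_node(node)
        data = multi.nodes[node]
        if "name" in data:
            names[node] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    n_ignored = 0
    # obonet edges run child -> parent keyed by relation type
    for child, parent, relation in multi.edges(keys=True):
        if child not in keep or parent not in keep:
            continue
        if relation not in KEPT_RELATIONS:
            n_ignored += 1
            continue
        dag.add_edge(parent, child, relation=relation)

    roots = [n for n in dag if dag.in_degree(n) == 0]
    if len(roots) != 1:
        raise OntologyError(
            f"namespace {ns} of {path} has {len(roots)} parentless terms: {sorted(roots)[:5]}"
        )
    graph = OntologyGraph(
        namespace=ns,
        dag=dag,
        root=roots[0],
        alt_ids=alt_ids,
        n_ignored_relations=n_ignored,
        names=names,
    )
    graph.validate()
    return graph


def write_obo(graph: OntologyGraph, path: str) -> None:
    """Serialize the graph back to OBO (round-trips nodes and edges)."""
    ns_long = NAMESPACES[graph.namespace][0]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: go\n\n")
        for term in sorted(graph.dag.nodes):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {graph.names.get(term, term)}\n")
            fh.write(f"namespace: {ns_long}\n")
            for alt, primary in sorted(graph.alt_ids.items()):
                if primary == term:
                    fh.write(f"alt_id: {alt}\n")
            for parent in sorted(graph.parents(term)):
                rel = graph.dag.edges[parent, term]["relation"]
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")


@dataclass
class AnnotationMap:
    """Gene → set of (term, evidence code) direct annotations."""

    namespace: str
    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    n_dropped_unknown: int = 0
    n_dropped_not: int = 0
    n_dropped_evidence: int = 0
    n_dropped_aspect: int = 0

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def direct_terms(self, gene: str) -> set[str]:
        """The directly annotated terms of ``gene`` (empty set if absent)."""
        return {t for t, _ in self.entries.get(gene, set())}

    def closed_terms(self, gene: str, graph: OntologyGraph) -> set[str]:
        """Direct terms plus all their ancestors (true-path rule)."""
        direct = self.direct_terms(gene)
        return ancestor_closure(direct, graph) if direct else set()

    def add(self, gene: str, term: str, evidence: str = "EXP") -> None:
        self.entries.setdefault(gene, set()).add((term, evidence.upper()))


GAF_COLUMNS = 17


def parse_gaf(
    path: str,
    graph: OntologyGraph,
    evidence_mode: str = "IEA+",
    gene_key: str = "symbol",
) -> AnnotationMap:
    """Read a GAF 2.x file, keeping rows in the graph's namespace.

    Parameters
    ----------
    evidence_mode:
        ``"IEA+"`` keeps all evidence codes; ``"IEA-"`` drops rows whose
        evidence code is IEA (electronically inferred).
    gene_key:
        ``"symbol"`` keys genes by column 3 (DB object symbol, the default),
        ``"id"`` by column 2 (DB object id).
    """
    mode = evidence_mode.strip().upper()
    if mode not in ("IEA+", "IEA-"):
        raise OntologyError(f"evidence_mode must be 'IEA+' or 'IEA-', got {evidence_mode!r}")
    if gene_key not in ("symbol", "id"):
        raise OntologyError(f"gene_key must be 'symbol' or 'id', got {gene_key!r}")
    aspect_letter = NAMESPACES[graph.namespace][1]
    key_col = 2 if gene_key == "symbol" else 1

    amap = AnnotationMap(namespace=graph.namespace)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != GAF_COLUMNS:
                raise OntologyError(
                    f"{path}:{lineno}: expected {GAF_COLUMNS} tab-separated columns, "
                    f"got {len(fields)}"
                )
            qualifier, term, evidence, aspect = fields[3], fields[4], fields[6].upper(), fields[8]
            if aspect != aspect_letter:
                amap.n_dropped_aspect += 1
                continue
            if "NOT" in qualifier.split("|"):
                amap.n_dropped_not += 1
                continue
            if mode == "IEA-" and evidence == "IEA":
                amap.n_dropped_evidence += 1
                continue
            term = graph.resolve(term)
            if term not in graph:
                amap.n_dropped_unknown += 1
                continue
            amap.add(fields[key_col], term, evidence)
    if not amap.entries:
        warnings.warn(f"no annotations kept from {path} (namespace {graph.namespace}, {mode})")
    return amap


def write_gaf(amap: AnnotationMap, path: str, db: str = "SYNTH") -> None:
    """Write the map as GAF 2.2 rows (17 columns, '!' header)."""
    aspect = NAMESPACES[amap.namespace][1]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in amap.genes:
            for term, evidence in sorted(amap.entries[gene]):
                row = [
                    db, gene, gene, "involved_in", term, "SYNTH:0000001",
                    evidence, "", aspect, gene, "", "gene", "taxon:0", "20200101",
                    db, "", "",
                ]
                fh.write("\t".join(row) + "\n")


def ancestor_closure(terms: set[str], graph: OntologyGraph) -> set[str]:
    """The input terms plus every ancestor of each (true-path closure).

    The root is always included for a nonempty input.  Raises
    :class:`OntologyError` naming the first term absent from the graph.
    """
    closed: set[str] = set()
    for term in terms:
        if term not in graph:
            raise OntologyError(f"term {term} is not in the {graph.namespace} graph")
        closed.add(term)
        closed |= graph.ancestors(term)
    return closed
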