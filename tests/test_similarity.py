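"""Gene–gene similarity measures and their shared invariants."""

import math

import networkx as nx
import numpy as np
import pytest

import stesim as st

from _oracles import brute_set_ic


@pytest.fixture(scope="module")
def fixture_setup(request):
    we = st.worked_example()
    amap = st.AnnotationMap(namespace="BP")
    amap.add("gene6", we.term("t_6"))
    amap.add("gene7", we.term("t_7"))
    amap.add("twin6", we.term("t_6"))
    amap.entries["bare"] = set()
    return we, amap


class TestSimSte:
    def test_identical_annotation_sets_score_one(self, fixture_setup):
        we, amap = fixture_setup
        assert st.sim_ste("gene6", "twin6", amap, we.graph, we.ic, we.omega) == 1.0

    def test_root_only_overlap_scores_zero(self, fixture_setup):
        we, _ = fixture_setup
        amap = st.AnnotationMap(namespace="BP")
        amap.add("a", we.term("t_1"))
        amap.add("b", we.term("t_8"))
        # closures meet only at the root, which carries no own IC
        assert st.sim_ste("a", "b", amap, we.graph, we.ic, we.omega) == 0.0

    def test_fixture_pair_matches_oracle_ratio(self, fixture_setup):
        """gene6/gene7 closures are {1,2,3,4,6} and {1,2,3,4,5,7}; the
        score is the brute-force set-IC ratio of {1,2,3,4} to {1..7}."""
        we, amap = fixture_setup
        inter = {we.term(f"t_{i}") for i in (1, 2, 3, 4)}
        union = {we.term(f"t_{i}") for i in range(1, 8)}
        expected = (brute_set_ic(inter, we.graph, we.ic, we.omega)
                    / brute_set_ic(union, we.graph, we.ic, we.omega))
        got = st.sim_ste("gene6", "gene7", amap, we.graph, we.ic, we.omega)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_unannotated_gene_is_nan_not_zero(self, fixture_setup):
        we, amap = fixture_setup
        assert math.isnan(st.sim_ste("gene6", "bare", amap, we.graph, we.ic, we.omega))

    def test_agrees_with_jaccard_when_own_ic_uniform(self):
        """With equal own-IC on every non-root term, the own-IC overlap
        ratio reduces to the Jaccard index over non-root terms."""
        dag = nx.DiGraph()
        for parent, child in [("GO:1", "GO:2"), ("GO:1", "GO:3"),
                              ("GO:2", "GO:4"), ("GO:3", "GO:5")]:
            dag.add_edge(parent, child, relation="is_a")
        g = st.OntologyGraph(namespace="BP", dag=dag, root="GO:1")
        g.validate()
        # IC built so that IC(t) - omega * IC(parent) = 0.2 everywhere
        omega = 0.5
        ic_vals = {"GO:1": 0.0}
        for t in ["GO:2", "GO:3", "GO:4", "GO:5"]:
            parent = next(iter(g.parents(t)))
            ic_vals[t] = omega * ic_vals[parent] + 0.2
        ic = st.ICTable(model="injected", values=ic_vals, normalized=False,
                        depth={}, N=5)
        w = st.EdgeWeightTable(weights={e: omega for e in
                                        [("GO:1", "GO:2"), ("GO:1", "GO:3"),
                                         ("GO:2", "GO:4"), ("GO:3", "GO:5")]},
                               ic_model="injected")
        amap = st.AnnotationMap(namespace="BP")
        amap.add("a", "GO:4")
        amap.add("b", "GO:5")
        got = st.sim_ste("a", "b", amap, g, ic, w)
        ca = st.ancestor_closure({"GO:4"}, g) - {"GO:1"}
        cb = st.ancestor_closure({"GO:5"}, g) - {"GO:1"}
        assert got == pytest.approx(len(ca & cb) / len(ca | cb), abs=1e-12)


class TestBaselines:
    def test_simui_fixture_value(self, fixture_setup):
        """Closures {t1..t4,t6} (5 terms) and {t1..t5,t7} (6 terms) share
        4 terms and their union has 7, so the Jaccard index is 4/7."""
        we, amap = fixture_setup
        assert st.sim_ui("gene6", "gene7", amap, we.graph) == pytest.approx(4 / 7)

    def test_vsm_fixture_value(self, fixture_setup):
        """Binary cosine of the same closures: 4 / sqrt(5 * 6)."""
        we, amap = fixture_setup
        expected = 4 / math.sqrt(5 * 6)
        assert st.sim_vsm("gene6", "gene7", amap, we.graph) == pytest.approx(expected)

    def test_vsm_always_positive_after_closure(self, synth_graph, synth_annotations):
        """Closed sets always share the root dimension, so the cosine can
        never be zero."""
        genes = synth_annotations.genes[:8]
        for a in genes:
            for b in genes:
                assert st.sim_vsm(a, b, synth_annotations, synth_graph) > 0.0

    def test_simgic_fixture_value(self, fixture_setup):
        """Plain-IC Jaccard on the published fixture ICs:
        (0 + 0.01 + 0.02 + 0.04) / 0.28 = 0.25."""
        we, amap = fixture_setup
        got = st.sim_gic("gene6", "gene7", amap, we.graph, we.ic)
        assert got == pytest.approx(0.07 / 0.28, abs=1e-12)

    def test_simgic_root_only_overlap_is_zero(self, fixture_setup):
        we, _ = fixture_setup
        amap = st.AnnotationMap(namespace="BP")
        amap.add("a", we.term("t_1"))
        amap.add("b", we.term("t_8"))
        assert st.sim_gic("a", "b", amap, we.graph, we.ic) == 0.0

    def test_jaccard_and_cosine_identical_sets(self, fixture_setup):
        we, amap = fixture_setup
        assert st.sim_ui("gene6", "twin6", amap, we.graph) == 1.0
        assert st.sim_vsm("gene6", "twin6", amap, we.graph) == 1.0
        assert st.sim_gic("gene6", "twin6", amap, we.graph, we.ic) == 1.0


class TestResnikBMA:
    def test_ancestor_pair_takes_ancestor_ic(self, fixture_setup):
        we, _ = fixture_setup
        amap = st.AnnotationMap(namespace="BP")
        amap.add("up", we.term("t_4"))
        amap.add("down", we.term("t_6"))
        # the most informative common ancestor of t_4 and t_6 is t_4 itself
        got = st.sim_resnik_bma("up", "down", amap, we.graph, we.ic)
        assert got == pytest.approx(we.ic[we.term("t_4")])

    def test_root_only_common_ancestor_scores_zero(self):
        dag = nx.DiGraph()
        dag.add_edge("GO:1", "GO:2", relation="is_a")
        dag.add_edge("GO:1", "GO:3", relation="is_a")
        g = st.OntologyGraph(namespace="BP", dag=dag, root="GO:1")
        g.validate()
        ic = st.ICTable(model="injected", values={"GO:1": 0.0, "GO:2": 0.9, "GO:3": 1.0},
                        normalized=True, depth={}, N=3)
        amap = st.AnnotationMap(namespace="BP")
        amap.add("a", "GO:2")
        amap.add("b", "GO:3")
        assert st.sim_resnik_bma("a", "b", amap, g, ic) == 0.0

    def test_singleton_self_similarity_is_own_ic(self, fixture_setup):
        """A gene annotated to one term scores IC of that term against
        itself (1 only for the maximally informative term)."""
        we, amap = fixture_setup
        got = st.sim_resnik_bma("gene6", "gene6", amap, we.graph, we.ic)
        assert got == pytest.approx(we.ic[we.term("t_6")])


class TestPairwiseMatrix:
    def test_identical_genes_give_unit_matrix(self, fixture_setup):
        we, amap = fixture_setup
        res = st.pairwise_matrix(["gene6", "twin6"], "ste", amap, we.graph,
                                 ic=we.ic, weights=we.omega)
        assert np.allclose(res.matrix, 1.0)

    def test_symmetry_and_flags(self, synth_graph, synth_annotations,
                                 synth_ic, synth_weights):
        genes = synth_annotations.genes[:10]
        res = st.pairwise_matrix(genes, "ste", synth_annotations, synth_graph,
                                 ic=synth_ic, weights=synth_weights)
        assert np.array_equal(res.matrix, res.matrix.T)
        long = res.to_long()
        assert len(long) == 10 * 11 // 2
        assert long["defined"].all()

    def test_unannotated_gene_flagged_undefined(self, fixture_setup):
        we, amap = fixture_setup
        res = st.pairwise_matrix(["gene6", "bare"], "simui", amap, we.graph)
        assert math.isnan(res.score("gene6", "bare"))
        long = res.to_long()
        assert not long[(long.gene_a == "bare") | (long.gene_b == "bare")]["defined"].any()

    def test_unknown_method_rejected(self, fixture_setup):
        we, amap = fixture_setup
        with pytest.raises(ValueError, match="unknown method"):
            st.pairwise_matrix(["gene6", "gene7"], "wang", amap, we.graph)


@pytest.mark.parametrize("method", sorted(st.METHODS))
def test_all_methods_bounded_symmetric_reflexive(method, synth_graph,
                                                 synth_annotations, synth_ic,
                                                 synth_weights):
    """Every method stays in [0, 1], is symmetric, and the group-wise
    methods give self-similarity exactly 1."""
    ic = (st.corpus_ic(synth_annotations, synth_graph) if method == "resnik"
          else synth_ic)
    genes = synth_annotations.genes[:12]
    res = st.pairwise_matrix(genes, method, synth_annotations, synth_graph,
                             ic=ic, weights=synth_weights)
    m = res.matrix
    assert np.nanmin(m) >= 0.0 and np.nanmax(m) <= 1.0 + 1e-12
    assert np.array_equal(m, m.T)
    if method != "resnik":
        assert np.allclose(np.diag(m), 1.0)
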