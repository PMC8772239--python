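import numpy as np
import pytest
from hypothesis import settings

import stesim as st

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def we():
    """The 8-term reference DAG with injected IC and edge weights."""
    return st.worked_example()


@pytest.fixture(scope="session")
def we_annotations(we):
    """Two genes annotated to the deep siblings t_6 and t_7, plus one to
    the root and one unannotated gene."""
    amap = st.AnnotationMap(namespace="BP")
    amap.add("gene6", we.term("t_6"))
    amap.add("gene7", we.term("t_7"))
    amap.add("generoot", we.term("t_1"))
    amap.entries["genenone"] = set()
    return amap


@pytest.fixture(scope="session")
def synth_graph():
    return st.generate_ontology(n_terms=120, max_depth=6, seed=11)


@pytest.fixture(scope="session")
def synth_annotations(synth_graph):
    return st.generate_annotations(synth_graph, n_genes=40, mean_terms=4, seed=11)


@pytest.fixture(scope="session")
def synth_ic(synth_graph):
    return st.ste_ic(synth_graph)


@pytest.fixture(scope="session")
def synth_weights(synth_graph, synth_ic):
    return st.edge_weights(synth_graph, synth_ic)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
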