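"""Compare the three IC models on a synthetic GO-like ontology.

The structural model scores a term from its depth, its ancestors' depths
and its descendant count; the corpus model from annotation frequency under
the true-path closure; the Sánchez model from leaf/subsumer counts.  All
are normalized to [0, 1] with IC(root) = 0.
"""

import numpy as np

import stesim as st

graph = st.generate_ontology(n_terms=500, max_depth=8, seed=0)
annotations = st.generate_annotations(graph, n_genes=100, seed=0)

for name, table in [
    ("structural", st.ste_ic(graph)),
    ("corpus", st.corpus_ic(annotations, graph)),
    ("sanchez", st.sanchez_ic(graph)),
]:
    vals = np.array(list(table.values.values()))
    edges, counts = st.ic_distribution(table, bins=10)
    mode = int(np.argmax(counts))
    print(f"{name:>10}: mean IC {vals.mean():.3f}, modal bin "
          f"[{edges[mode]:.1f}, {edges[mode + 1]:.1f}), "
          f"{counts[mode]} of {counts.sum()} terms")

print("\nThe structural model concentrates mass at intermediate IC values —")
print("most ontology terms sit at middle depths and carry medium specificity.")
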