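# Methods

## Scope and model

`stesim` measures gene functional similarity over a single GO namespace
(BP, CC or MF) treated as a rooted DAG with `is_a` and `part_of` edges.
Other relation types (`regulates`, `occurs_in`, …) are dropped at parse
time with a count: they cross semantic boundaries that the true-path rule
does not license, and the downstream equations are defined over the
subsumption hierarchy only. `part_of` is treated identically to `is_a`
throughout — every formula here is relation-agnostic.

The pipeline is: term IC → edge weights → inherited/own decomposition →
set IC → gene similarity. Genes enter through GAF 2.x annotations; the
true-path rule (a gene annotated to a term is annotated to all its
ancestors) is applied as an explicit ancestor closure before any set
operation, which is also what makes every parent lookup in the
decomposition total.

## Numerical conventions

Several conventions are needed that a formula sheet alone does not fix;
they are isolated here and in the code at single configuration points.

- **Logarithm base.** Natural log everywhere. Every downstream quantity is
  either a ratio or max-normalized, so the base only rescales.
- **Depth.** Longest root→term path counted in nodes, so depth(root) = 1.
  This makes the first factor of the structural IC vanish at the root,
  giving IC(root) = 0 under every model.
- **Descendant counts in term IC.** The third factor uses |Desc(t)| + 1
  with Desc excluding the term itself. Without the +1 the factor is
  undefined for leaves; with it, leaves get the maximal specificity factor
  1, consistent with deeper terms being more specific.
- **Ancestors.** Ance(t) excludes t. The root's empty ancestor sum never
  evaluates because the root's IC is already 0 via the first factor.
- **Normalization.** Raw structural IC is unbounded, so `normalize=True`
  (the default) divides by the maximum, giving values in [0, 1] with max
  exactly 1. Raw mode is kept for closed-form oracle tests.
- **Edge weights.** Both descendant sums in ω are self-inclusive. With
  exclusive sums every leaf-targeting edge would have numerator 0 and the
  decomposition would degenerate (leaves inheriting nothing); inclusion
  yields ω ∈ (0, 1] because the numerator's term set is a subset of the
  denominator's. An all-zero-IC subtree (denominator 0) gets ω = 1.
- **Own-IC clamping.** A multi-parent term can inherit more than its own
  IC; own values are clamped at 0 and the clamp is flagged. Set IC sums
  own values as non-negative semantic increments, and clamping is what
  preserves monotonicity of set IC under set growth.
- **Corpus IC of never-annotated terms.** p(t) = 0 gives infinite IC;
  such terms are assigned the maximum observed IC and flagged, keeping
  downstream arithmetic finite.
- **Rounding.** All arithmetic is full precision. The 3-decimal half-up
  rounding in `set_ic_trace` exists only to reproduce the hand-calculation
  style of the worked example, where each step is rounded before
  accumulation (hence 0.208 in the trace vs 0.2064 exact).
- **Tie-breaking.** Trace steps follow a lexicographic topological order,
  which makes traces deterministic; the set-IC value itself is provably
  order-invariant because inherited IC depends only on parents' full IC.
- **Undefined similarity.** A gene with no annotations has no similarity;
  scalar functions return NaN (never 0, which is a meaningful score) and
  the evaluation harness drops such pairs with a reported count.
- **Degenerate similarity.** If both closed sets carry zero set-IC (e.g.
  both are {root}), the own-IC ratio is 0/0; identical sets score 1,
  otherwise NaN.

## Worked example fixture

The 8-term reference DAG ships with its published term-IC and edge-weight
tables injected rather than recomputed: those weights were derived on the
full ontology, and restricting the ω formula to the 8-node excerpt does not
reproduce them under any self-inclusion convention. The fixture therefore
validates the decomposition and accumulation stages, with IC and ω as
given inputs.

## Synthetic data generator

`generate_ontology` emulates the large-scale shape of a GO namespace: a
single root, levels whose sizes follow a binomial (interior-peaked)
profile — in the real GO, terms at intermediate depths are the large
majority — growth between levels capped by a branching factor (default 3),
and a 0.3 default probability that a term gains a second, strictly
shallower parent (real GO terms frequently have multiple parents). Default
size is 500 terms over 8 levels, commensurate with the CC namespace's
order of magnitude while keeping test runtimes in seconds.

`generate_annotations` emulates GOA structure: each of 100 genes (default)
draws Poisson(4)+1 distinct direct terms with probability proportional to
depth squared — real annotation concentrates on specific terms — and each
annotation is evidence-coded IEA with probability 0.4 (real GOA is
dominated by electronic annotations), otherwise EXP, supporting IEA+/IEA−
stratification tests.

What the generator does *not* emulate: term-name text, correlated
annotation between related genes beyond what shared term sampling induces,
namespace-specific topology differences, and annotation depth/breadth
heterogeneity across genes. Passing tests therefore demonstrate
correctness of the computations and their invariants, not performance
claims on real PPI or expression benchmarks — those depend on specific
GO/GOA/benchmark releases and are out of scope; the evaluation module
reproduces the protocols (AUC, Pearson, class separation), and its tests
are property-based (null behavior, separation on constructed signal).

## Problem sizes

Tests run on ontologies of 100–500 terms and 40–100 genes; oracle
equivalence uses 100 random DAGs of ≤ 12 nodes checked at 1e-12 against
exhaustive parent enumeration; statistical nulls use 10^4 pairs. These
sizes give stable statistics in seconds on one CPU.

## Known limitations

- Single-namespace only; no cross-ontology similarity.
- OBO and GAF input only (no OWL/RDF), no release management.
- The Resnik baseline uses direct annotation sets with best-match
  averaging and a normalized corpus IC; self-similarity of a gene under
  Resnik equals the IC of its terms, not 1 — inherent to the measure.
- Edge weights are recomputed per (graph, IC model) pair; there is no
  persistent cache across processes beyond the CLI's explicit exports.
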