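# Methods

## Ontology model

The ontology is a forest of category trees whose nodes are identified
by dot-separated tree numbers; the component count of a tree number is
the node's depth, and its prefixes name all of its ancestors. Category
roots therefore have depth 1. A synthetic **virtual root** of depth 0
and IC 0 joins the category trees so that every node pair has a least
common ancestor and a finite path length; this makes all six measures
total functions, with WP/Res/Lin/Sch evaluating to 0 across categories.
Ancestors implied by a prefix but absent from the input are
materialised as unnamed nodes and counted in `T_total` — in a real
tree-number ontology those nodes necessarily exist.

Information content is structural:
`IC(v) = H(v)·(1 − log(|C(v)|+1)/log(T_total))`. `|C(v)|` counts
**direct** children by default; `children_mode="descendants"` switches
to the full descendant count for users who prefer subtree-mass
specificity. The expression is a ratio of logarithms and therefore
log-base invariant; natural logs are used internally. Leaves get
`IC = H`, so Resnik similarity is unbounded above by the maximum leaf
depth rather than by 1. `T_total < 2` makes the formula degenerate
(`log T_total ≤ 0`) and raises an error.

The maximum depth `D` used by the LC measure is the global maximum over
all loaded nodes, not a per-category maximum: the formula needs one
normalising constant per ontology, and the global reading keeps LC
comparable across category boundaries.

## Measures and degenerate cases

SP and LC are defined on heading pairs via the shortest/longest path
lengths `L_min`/`L_max` over all node pairs of the two headings —
including cross-category pairs routed through the virtual root — while
WP, Res, Lin and Sch are defined on node pairs and lifted to headings
by AMM. The dispatch follows these signatures as printed; no
restriction of `L_min`/`L_max` to same-category pairs is applied.

Degenerate cases are resolved once, in favour of the measure's intent:

* `SP` with `L_max = 0` (two identical single-node headings) is 0/0 by
  the formula; identical headings are maximally similar, so 1.
  Note SP is a *spread* score: any two single-node headings score 0
  because `L_min = L_max` regardless of distance.
* `Lin`/`Sch` with `IC(v) + IC(v') = 0` return 0.
* Self-similarity is exactly 1 for WP, SP, LC and Lin (when IC > 0);
  `Sch(v, v) = 1 − e^{−IC(v)} < 1` and `Res(v, v) = IC(v)` by
  construction.

## Engine

The three stages are pure functions over key-value pairs, so the
distributed execution model reduces to in-process composition without
changing semantics:

* **Inversion** emits `<heading, doc>` per incidence and groups by
  heading.
* **Heading table**: all `k(k+1)/2` unordered pairs, partitioned
  round-robin over `workers`; the merged table is independent of the
  partitioning.
* **Document similarity**: for each heading `m` and document `d'`, the
  best match `Sim(m, d')` is computed once and emitted toward every
  pair `(d, d')` with `m ∈ d`, keyed by the lexicographically ordered
  pair so both AMM directions meet at one reduce key. Reduce divides
  the per-key sum by `|d| + |d'|`, with the heading counts recovered
  from the corpus rather than carried in the values (smaller
  intermediates). Self-pairs are never emitted; the diagonal is set to
  1 directly (a raw-diagonal flag exists for Res, whose self-similarity
  is IC-scaled), giving clustering a consistent self-affinity.

Numerical policy: per-key contributions are summed in sorted order, so
the matrix is bit-for-bit identical for any worker count when the
combiner is off; the combiner introduces per-partition partial sums and
agrees within 1e-9. `workers` controls partitioning only;
`processes=True` additionally runs partitions in an OS process pool
(same output, useful on multicore machines). Instrumented counters
verify the map stage performs exactly `k·n` heading-to-document
evaluations and at most `n(n−1)/2` reduce keys.

## Clustering and NMI

The similarity matrix is clustered three ways: spectral clustering on
the matrix as a precomputed affinity; agglomerative clustering with
**average linkage** (a robust default for similarity-derived distances;
the linkage is otherwise a free choice) on `dist = 1 − sim`, with
similarities first rescaled by their maximum when it exceeds 1 (Res);
and k-means on the rows of the similarity matrix as feature vectors —
the simplest faithful reading of "clustering the similarity". The
cluster count `k` is user-supplied (taken from the known topic count in
evaluations); all stochastic algorithms take an explicit seed,
default 0. Res matrices are clustered raw by default; an optional
normalisation rescales off-diagonal values to [0, 1] first.

NMI uses the sqrt normalisation
`NMI = Σ n_hl·log(n·n_hl/(n_h·n_l)) / sqrt(Σ n_h·log(n_h/n) · Σ n_l·log(n_l/n))`;
both denominator sums are non-positive, so their product is
non-negative under the radical. Zero cells contribute 0; term arrays
are summed in sorted order, making the score exactly invariant under
label permutation. When either labeling is single-class the
normalisation is undefined and NaN is returned as an explicit flag.

## Synthetic fixtures

`simulate.FixtureSpec` generates the test-bed: a random forest
(default 3 categories, branching 2–3, depth ≤ 4, ≈ 40–100 nodes) with
36 named headings spread evenly across categories, some carrying 1–2
extra tree numbers from the same category as real multi-position
headings do. Topics are anchored to disjoint category subtrees; each
document draws 4–8 headings without replacement, from its topic's
subtree with probability `within_topic_prob` (default 0.9, a strongly
but not perfectly topical collection) and uniformly from the other
subtrees otherwise. With equal category counts,
`within_topic_prob = 1/n_topics` makes the draw distribution identical
across topics and the labels uninformative — the null model.

What this emulates, and what it does not: the generator reproduces the
*structural* situation — multi-position headings, topic-concentrated
annotation, disjoint subtrees — but real MeSH annotation has heading
frequencies spanning orders of magnitude (check tags like "Humans"
appear almost everywhere), topics overlap in the tree, and the real
ontology is far deeper and wider. Passing the planted-recovery tests
therefore demonstrates the pipeline's correctness and its ability to
exploit genuine subtree separation, not a clustering accuracy claim for
real literature collections.

Evaluation problem sizes (chosen so the whole suite re-runs in well
under a minute apiece): oracle-equivalence over 30 random corpora of up
to 60 documents and 40 headings; recovery over 20 corpora of 3×30
documents; the null at n = 201 over 5 seeds; measure properties over
more than 1000 random pairs.

## Known limitations

* Corpus lines resolve comma-containing heading names by greedy
  longest-first matching against the registered vocabulary; an
  unregistered heading in a corpus line is an error rather than an
  unknown-token fallback.
* The engine holds the corpus, heading table, and all emitted
  contributions in memory; it parallelises the paper-shaped
  decomposition but does not stream intermediates to disk.
* Qualifier terms, supplementary concept records, and the MeSH XML
  dialect are out of scope; only `MH`/`MN` fields of the descriptor
  ASCII format are read.
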