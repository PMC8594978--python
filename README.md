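# meshsim

Semantic similarity and clustering for document collections annotated
with hierarchical ontology headings.

Biomedical documents in MEDLINE are indexed with MeSH headings —
controlled-vocabulary concepts placed at one or more positions of a
category-tree forest, each position written as a dot-separated *tree
number* such as `G02.111.222`. Because the headings summarise what a
document is about, the semantic similarity of two documents can be
measured entirely in the ontology, without looking at their text. Doing
that pair by pair is quadratic in both documents and headings and
becomes the bottleneck long before clustering does; `meshsim`
restructures the computation as a map/shuffle/reduce pipeline that
evaluates every heading-to-document best match exactly once, then
clusters the resulting similarity matrix and scores the clusters
against known labels. It is aimed at text-mining practitioners who want
ontology-based document clustering at collection scale, and at anyone
who needs a transparent, testable reference for the underlying
similarity measures.

## The model

A document is a set of headings, `d = {m_1, …}`; a heading is a set of
ontology nodes, `m = {v_1, …}`. Node-level similarity is lifted to
documents by **average maximum match** (AMM): each element is matched
with its best counterpart in the opposite set, and both directions are
averaged,

    Sim(d, d') = [ Σ_{m∈d} Sim(m, d') + Σ_{m'∈d'} Sim(m', d) ] / (|d| + |d'|)
    Sim(m, d)  = max_{m'∈d} Sim(m, m')
    Sim(m, m') = [ Σ_{v∈m} max_{v'∈m'} Sim(v, v') + Σ_{v'∈m'} max_{v∈m} Sim(v', v) ] / (|m| + |m'|)

Six interchangeable measures feed this aggregation. Four act on node
pairs — Wu–Palmer `WP = 2·depth(lca) / (depth(v) + depth(v'))`, Resnik
`Res = IC(lca)`, Lin `Lin = 2·IC(lca) / (IC(v) + IC(v'))`, and
Schlicker `Sch = Lin · (1 − e^{−IC(lca)})` — and two act directly on
heading pairs through path statistics: the relative path spread
`SP = (L_max − L_min) / L_max` and `LC = 1 − log(1 + L_min) / log(1 + 2D)`,
with `D` the maximum depth of the loaded ontology. Information content
is structural (no corpus counts needed):

    IC(v) = H(v) · (1 − log(|C(v)| + 1) / log(T_total))

where `H(v)` is the node's depth, `C(v)` its children, and `T_total`
the node count of the forest.

The engine computes the full matrix in three stages with identical
semantics to a distributed key-value job: corpus inversion
(`heading → [docs]`), precomputation of all heading-pair similarities,
and a map stage that evaluates `Sim(m, d')` once per heading and
document (`k·n` evaluations instead of the naive `O(m²n²)`), emitting
contributions keyed by canonical document pair; reduce normalises each
pair's summed contributions by `|d| + |d'|`. An optional pre-shuffle
combiner compacts the intermediate data without changing any result.
The output is contractually identical to the brute-force pairwise
computation for any worker count.

## Worked example

A five-node toy ontology (one category `A` with children `A.1`, `A.2`,
and grandchildren `A.1.1`, `A.1.2`) with headings `m1 = {A.1.1}` and
`m2 = {A.1.2, A.2}`:

```python
from meshsim import (build_ontology, Corpus, Document,
                     sim_wp, sim_lin, heading_sim, run_docsim)

ont = build_ontology([("hA", ["A"]), ("h1", ["A.1"]), ("h2", ["A.2"]),
                      ("h11", ["A.1.1"]), ("h12", ["A.1.2"]),
                      ("m1", ["A.1.1"]), ("m2", ["A.1.2", "A.2"])])

print(ont.information_content("A.1"))     # 0.6347876110280293
print(sim_wp(ont, "A.1.1", "A.1.2"))      # 0.6666666666666666
print(sim_lin(ont, "A.1.1", "A.1.2"))     # 0.21159587034267643
print(heading_sim(ont, "WP", "m1", "m2")) # 0.5777777777777778

corpus = Corpus([Document("d1", frozenset({"m1"})),
                 Document("d2", frozenset({"m2"}))])
print(run_docsim(ont, "WP", corpus).values)
# [[1.         0.57777778]
#  [0.57777778 1.        ]]
```

Reading the numbers: `A.1` is an internal node with two children in a
five-node forest, so its structural IC is well below its depth of 2;
the sibling leaves `A.1.1`/`A.1.2` share the parent `A.1` at depth 2 of
their depth-3 paths, giving Wu–Palmer 2·2/6 = 2/3; the AMM heading
similarity 0.578 averages that best match with the weaker `A.1.1`–`A.2`
match (2/5); and the two single-heading documents inherit exactly that
value as their similarity.

The same flow is available from the shell:

```bash
meshsim simulate --seed 0 --out-dir fixture          # synthetic ontology + corpus + labels
meshsim pipeline --ontology fixture/ontology.tsv \
    --corpus fixture/corpus.txt --labels fixture/labels.tsv \
    --measure WP --k 3 --out-dir out
# NMI = 1.000000
```

Real MeSH can be loaded from the descriptor ASCII format
(`MH =` / `MN =` fields) or from a two-column TSV.

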