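"""Synthetic ontologies and planted-topic corpora.

Real heading-annotated collections (MEDLINE documents tagged with MeSH
headings) cannot be shipped, so every pipeline stage is exercised on
generated stand-ins with a known answer:

* :func:`make_ontology` grows a random forest of tree-number nodes and
  names a subset of them as headings (optionally with several tree
  numbers each, like real MeSH headings).
* :func:`make_corpus` plants topic structure: each topic is anchored to
  a disjoint category subtree, and each document draws its headings
  from its topic's subtree with probability ``within_topic_prob``, else
  uniformly from the other subtrees.  The true topic labels are
  returned alongside the corpus, giving a cluster-recovery benchmark
  with a single separation knob.

At ``within_topic_prob = 1/n_topics`` (and topic pools of equal
standing) the draw distribution is identical for every topic, so the
labels carry no signal and pipeline NMI should be near zero.

All randomness flows through one :class:`numpy.random.Generator` seeded
from ``FixtureSpec.seed``; fixed seed means byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .aggregation import Corpus, Document
from .ontology import Ontology


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic ontology + corpus.

    Defaults emulate a small topical document collection: 3 category
    trees of depth up to 4 with branching 2-3 (~40-100 nodes), 36 named
    headings, 3 topics of 30 documents, 4-8 headings per document, and
    90% of a document's headings drawn from its own topic subtree.
    """

    seed: int = 0
    n_categories: int = 3
    branching: tuple[int, int] = (2, 3)
    max_depth: int = 4
    n_headings: int = 36
    n_topics: int = 3
    docs_per_topic: int = 30
    headings_per_doc: tuple[int, int] = (4, 8)
    within_topic_prob: float = 0.9
    multi_node_prob: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_topic_prob <= 1.0:
            raise FixtureError("within_topic_prob must be in [0, 1]")
        if self.max_depth < 2:
            raise FixtureError("max_depth must be >= 2")
        if self.headings_per_doc[0] < 1 or self.headings_per_doc[0] > self.headings_per_doc[1]:
            raise FixtureError("headings_per_doc must be a non-empty range with min >= 1")
        if self.n_topics > self.n_categories:
            raise FixtureError("n_topics must not exceed n_categories")
        if self.branching[0] < 1 or self.branching[0] > self.branching[1]:
            raise FixtureError("branching must be a range with min >= 1")


def make_ontology(spec: FixtureSpec) -> Ontology:
    """Grow a random forest and name ``n_headings`` nodes as headings.

    Heading names are ``H000``-style; with probability
    ``multi_node_prob`` a heading receives 1-2 extra tree numbers drawn
    from the same category (real headings sit at several positions, and
    keeping the extras in-category preserves topic separation).
    """
    rng = np.random.default_rng(spec.seed)
    ontology = Ontology()
    category_nodes: list[list[str]] = []
    for c in range(spec.n_categories):
        root = f"C{c + 1}"
        ontology.add_tree_number(root)
        nodes = [root]
        frontier = [root]
        for _ in range(spec.max_depth - 1):
            next_frontier = []
            for parent in frontier:
                n_children = int(rng.integers(spec.branching[0], spec.branching[1] + 1))
                for i in range(n_children):
                    child = f"{parent}.{i + 1}"
                    ontology.add_tree_number(child)
                    nodes.append(child)
                    next_frontier.append(child)
            frontier = next_frontier
        category_nodes.append(nodes)

    all_nodes = [t for nodes in category_nodes for t in nodes]
    if spec.n_headings > len(all_nodes):
        raise FixtureError(
            f"cannot name {spec.n_headings} headings on {len(all_nodes)} nodes"
        )
    category_of = {t: c for c, nodes in enumerate(category_nodes) for t in nodes}
    # spread headings evenly across categories so each topic subtree gets
    # a comparable vocabulary (balanced pools, like balanced topics)
    quotas = [spec.n_headings // spec.n_categories] * spec.n_categories
    for i in range(spec.n_headings % spec.n_categories):
        quotas[i] += 1
    primaries: list[str] = []
    for c, quota in enumerate(quotas):
        if quota > len(category_nodes[c]):
            raise FixtureError(
                f"category {c + 1} has {len(category_nodes[c])} nodes, "
                f"fewer than its {quota} heading quota"
            )
        primaries.extend(rng.choice(category_nodes[c], size=quota, replace=False).tolist())
    primaries = sorted(primaries)
    for i, primary in enumerate(primaries):
        ids = [primary]
        if rng.random() < spec.multi_node_prob:
            pool = [t for t in category_nodes[category_of[primary]] if t != primary]
            extra = int(rng.integers(1, 3))
            if pool:
                ids.extend(
                    rng.choice(pool, size=min(extra, len(pool)), replace=False).tolist()
                )
        ontology.register_heading(f"H{i:03d}", ids)
    return ontology


def _topic_pools(spec: FixtureSpec, ontology: Ontology) -> list[list[str]]:
    """Heading names grouped by the category of their first tree number."""
    pools: list[list[str]] = [[] for _ in range(spec.n_categories)]
    for name in sorted(ontology.headings):
        heading = ontology.headings[name]
        category = min(heading.node_ids).split(".")[0]
        pools[int(category[1:]) - 1].append(name)
    return pools


def make_corpus(spec: FixtureSpec, ontology: Ontology) -> tuple[Corpus, dict[str, int]]:
    """Plant ``n_topics`` document groups over disjoint category subtrees.

    Returns the corpus and the true label of each document.  Headings
    are sampled without replacement within a document (documents are
    heading sets).  Raises :class:`FixtureError` when a topic subtree
    holds fewer headings than the largest document needs.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pools = _topic_pools(spec, ontology)[: spec.n_topics]
    lo, hi = spec.headings_per_doc
    for t, pool in enumerate(pools):
        if len(pool) < hi:
            raise FixtureError(
                f"topic {t} subtree has {len(pool)} headings; documents need up to {hi}"
            )
    all_pools = _topic_pools(spec, ontology)
    documents: list[Document] = []
    labels: dict[str, int] = {}
    doc_index = 0
    for topic in range(spec.n_topics):
        own = pools[topic]
        other = sorted(
            h for t, pool in enumerate(all_pools) for h in pool if t != topic
        )
        for _ in range(spec.docs_per_topic):
            size = int(rng.integers(lo, hi + 1))
            chosen: list[str] = []
            for _ in range(size):
                in_topic = rng.random() < spec.within_topic_prob
                pool = [h for h in (own if in_topic else other) if h not in chosen]
                if not pool:
                    pool = [h for h in (other if in_topic else own) if h not in chosen]
                if not pool:
                    break
                chosen.append(pool[int(rng.integers(len(pool)))])
            doc_id = f"d{doc_index:04d}"
            documents.append(Document(doc_id=doc_id, headings=frozenset(chosen)))
            labels[doc_id] = topic
            doc_index += 1
    return Corpus(documents), labels


def make_fixture(spec: FixtureSpec) -> tuple[Ontology, Corpus, dict[str, int]]:
    """Convenience wrapper: ontology + planted corpus + true labels."""
    ontology = make_ontology(spec)
    corpus, labels = make_corpus(spec, ontology)
    return ontology, corpus, labels


def null_spec(spec: FixtureSpec) -> FixtureSpec:
    """The chance-level variant: topic labels carry no information."""
    return replace(spec, within_topic_prob=1.0 / spec.n_topics)
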