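import numpy as np
import pytest

from meshsim import Corpus, Document, build_ontology
from meshsim.simulate import FixtureError, FixtureSpec, make_fixture

# Small hand-checkable ontology: one category tree
#   A -> {A.1, A.2}, A.1 -> {A.1.1, A.1.2};  T_total = 5, D = 3.
# Headings name every node; m1/m2 are the worked multi-node examples.
TOY_RECORDS = [
    ("hA", ["A"]),
    ("h1", ["A.1"]),
    ("h2", ["A.2"]),
    ("h11", ["A.1.1"]),
    ("h12", ["A.1.2"]),
    ("m1", ["A.1.1"]),
    ("m2", ["A.1.2", "A.2"]),
]


@pytest.fixture
def toy():
    return build_ontology(TOY_RECORDS)


@pytest.fixture
def toy_corpus():
    return Corpus(
        [
            Document("d1", frozenset({"m1"})),
            Document("d2", frozenset({"m2"})),
        ]
    )


def random_fixture(seed, max_docs=60, max_headings=40):
    """A random planted-topic ontology + corpus, deterministic in `seed`.

    Sizes stay within n <= max_docs documents, k <= max_headings
    headings, and well under 300 ontology nodes.  Specs that come out
    infeasible (too few nodes or too small topic pools) are rerolled
    deterministically.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        n_categories = int(rng.integers(2, 5))
        n_topics = int(rng.integers(2, n_categories + 1))
        spec = FixtureSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_categories=n_categories,
            branching=(int(rng.integers(1, 3)), 3),
            max_depth=int(rng.integers(3, 5)),
            n_headings=int(rng.integers(8, max_headings + 1)),
            n_topics=n_topics,
            docs_per_topic=int(rng.integers(2, max(3, max_docs // n_topics + 1))),
            headings_per_doc=(2, int(rng.integers(3, 6))),
            within_topic_prob=float(rng.uniform(0.3, 0.95)),
        )
        try:
            return make_fixture(spec)
        except FixtureError:
            continue
    raise RuntimeError(f"could not draw a feasible fixture from seed {seed}")
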