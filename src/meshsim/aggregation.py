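"""Average maximum match (AMM) aggregation from nodes to documents.

A document is a set of headings; a heading is a set of ontology nodes.
AMM lifts a node-level similarity to sets in two steps, each time
matching every element with its best counterpart in the opposite set
and averaging over both directions:

    Sim(m, m')  = [ sum_{v in m} max_{v' in m'} Sim(v, v')
                  + sum_{v' in m'} max_{v in m} Sim(v', v) ]
                  / (|m| + |m'|)

    Sim(m, d)   = max_{m' in d} Sim(m, m')

    Sim(d, d')  = [ sum_{m in d} Sim(m, d')
                  + sum_{m' in d'} Sim(m', d) ]
                  / (|d| + |d'|)

Heading-level measures (SP, LC) skip the first step and feed their
direct heading similarity into the document aggregation.

This module also provides the naive pair-by-pair document similarity
matrix, which serves as the correctness oracle for the map/reduce
engine in :mod:`meshsim.mapreduce`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Protocol

import numpy as np

from .measures import Measure, heading_level_sim, node_sim
from .ontology import Ontology, OntologyError


class CorpusError(ValueError):
    """Raised for invalid documents or corpora."""


@dataclass(frozen=True)
class Document:
    """A document identified by ``doc_id`` carrying a set of heading names.

    Duplicate headings are collapsed: a document is a *set* of semantic
    features, and the AMM denominator counts distinct headings.
    """

    doc_id: str
    headings: frozenset[str]

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("document id must be non-empty")
        if not self.headings:
            raise CorpusError(f"document {self.doc_id!r} has no headings")

    @property
    def mesh_number(self) -> int:
        return len(self.headings)


class Corpus:
    """An ordered collection of documents with unique ids."""

    def __init__(self, documents: Iterable[Document]) -> None:
        self.documents: list[Document] = list(documents)
        self._by_id: dict[str, Document] = {}
        for doc in self.documents:
            if doc.doc_id in self._by_id:
                raise CorpusError(f"duplicate document id {doc.doc_id!r}")
            self._by_id[doc.doc_id] = doc

    @property
    def doc_ids(self) -> list[str]:
        return [doc.doc_id for doc in self.documents]

    def heading_vocabulary(self) -> list[str]:
        """Sorted list of all heading names occurring in the corpus."""
        vocab: set[str] = set()
        for doc in self.documents:
            vocab.update(doc.headings)
        return sorted(vocab)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, doc_id: str) -> Document:
        try:
            return self._by_id[doc_id]
        except KeyError:
            raise CorpusError(f"unknown document id {doc_id!r}") from None

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._by_id

    def __repr__(self) -> str:
        return f"Corpus(n={len(self)}, k={len(self.heading_vocabulary())})"


class SimTable(Protocol):
    """Anything that can look up a precomputed heading-pair similarity."""

    def lookup(self, m: str, m2: str) -> float: ...


def heading_sim(
    ontology: Ontology,
    measure: Measure | str,
    m: str,
    m2: str,
    children_mode: str = "direct",
) -> float:
    """Similarity of two headings under a measure.

    Heading-level measures (SP, LC) evaluate their formula directly;
    node-level measures are aggregated over the headings' node sets by
    AMM.  Symmetric in ``m`` and ``m2``.
    """
    measure = Measure.from_name(measure)
    if measure.is_heading_level:
        return heading_level_sim(ontology, measure, m, m2)
    a = ontology.heading(m).node_ids
    b = ontology.heading(m2).node_ids
    forward = sum(
        max(node_sim(ontology, measure, v, v2, children_mode) for v2 in b) for v in a
    )
    backward = sum(
        max(node_sim(ontology, measure, v2, v, children_mode) for v in a) for v2 in b
    )
    return (forward + backward) / (len(a) + len(b))


def heading_to_doc_sim(m: str, doc: Document, table: SimTable) -> float:
    """Best match of heading ``m`` against the headings of ``doc``."""
    return max(table.lookup(m, m2) for m2 in doc.headings)


def doc_sim(d: Document, d2: Document, table: SimTable) -> float:
    """AMM document similarity from a complete heading-pair table."""
    forward = sum(heading_to_doc_sim(m, d2, table) for m in d.headings)
    backward = sum(heading_to_doc_sim(m2, d, table) for m2 in d2.headings)
    return (forward + backward) / (d.mesh_number + d2.mesh_number)


@dataclass
class DocSimMatrix:
    """Dense symmetric document similarity matrix with unit diagonal."""

    doc_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.doc_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")

    def sim(self, doc_id: str, doc_id2: str) -> float:
        i = self.doc_ids.index(doc_id)
        j = self.doc_ids.index(doc_id2)
        return float(self.values[i, j])

    @property
    def n(self) -> int:
        return len(self.doc_ids)


class _DictTable:
    """Minimal in-memory heading-pair cache used by the brute-force oracle."""

    def __init__(self, ontology: Ontology, measure: Measure, children_mode: str) -> None:
        self._ontology = ontology
        self._measure = measure
        self._children_mode = children_mode
        self._cache: dict[tuple[str, str], float] = {}

    def lookup(self, m: str, m2: str) -> float:
        key = (m, m2) if m <= m2 else (m2, m)
        value = self._cache.get(key)
        if value is None:
            value = heading_sim(self._ontology, self._measure, key[0], key[1], self._children_mode)
            self._cache[key] = value
        return value


def doc_sim_matrix_bruteforce(
    ontology: Ontology,
    measure: Measure | str,
    corpus: Corpus,
    children_mode: str = "direct",
    unit_diagonal: bool = True,
) -> DocSimMatrix:
    """Pair-by-pair document similarity: the traditional O(n^2) baseline.

    Kept deliberately simple and independent of the map/reduce engine so
    it can serve as that engine's correctness oracle.  The diagonal is
    fixed to 1 unless ``unit_diagonal=False``, in which case the raw
    self-similarity of the aggregation is reported (relevant for Res,
    whose self-similarity is IC-scaled).
    """
    if len(corpus) == 0:
        raise CorpusError("corpus is empty")
    measure = Measure.from_name(measure)
    table = _DictTable(ontology, measure, children_mode)
    n = len(corpus)
    values = np.zeros((n, n), dtype=float)
    docs = corpus.documents
    for i in range(n):
        values[i, i] = 1.0 if unit_diagonal else doc_sim(docs[i], docs[i], table)
        for j in range(i + 1, n):
            s = doc_sim(docs[i], docs[j], table)
            values[i, j] = values[j, i] = s
    return DocSimMatrix(doc_ids=corpus.doc_ids, values=values)
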