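"""Map/shuffle/reduce decomposition of pairwise document similarity.

The naive approach computes every document pair independently, which
recomputes each heading-to-document best match many times.  The engine
here removes that redundancy with three stages built from pure
functions, mirroring a distributed key-value pipeline:

1. **Corpus inversion** (:func:`transform_corpus`): lines
   ``doc#h1,h2,...`` become an inverted index ``heading -> [docs]``.
2. **Heading-pair precompute** (:func:`precompute_heading_table`): all
   ``k(k+1)/2`` unordered heading similarities, partitioned across
   workers.
3. **Document similarity** (:func:`run_docsim`): for each heading ``m``
   and each document ``d'`` the best match ``Sim(m, d')`` is evaluated
   exactly once and emitted toward every pair ``(d, d')`` with
   ``m in d`` — giving ``k * n`` map evaluations in place of the naive
   ``O(m^2 n^2)``.  Shuffle groups contributions by canonical document
   pair; reduce divides the summed contributions by ``|d| + |d'|``.

An optional pre-shuffle combiner aggregates per-partition partial sums;
it never changes the reduced result.  Contributions are summed in
sorted order per key, so the output is independent of partitioning and
bit-for-bit reproducible when no combiner is used.  ``workers`` selects
the number of partitions; ``processes=True`` additionally executes the
partitions in an OS process pool.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .aggregation import Corpus, CorpusError, DocSimMatrix, doc_sim, heading_sim
from .measures import Measure
from .ontology import Ontology


class TableIncompleteError(KeyError):
    """A heading pair required by the reduce stage is missing from the table."""


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical unordered document pair; never a self-pair.

    Both summation directions of the AMM numerator must land on one
    reduce key, hence the canonical (low, high) ordering.
    """

    low: str
    high: str

    @classmethod
    def of(cls, a: str, b: str) -> "PairKey":
        if a == b:
            raise ValueError(f"self-pair {a!r} is never emitted")
        return cls(a, b) if a < b else cls(b, a)


@dataclass
class InvertedIndex:
    """Heading -> sorted list of ids of the documents containing it."""

    entries: dict[str, list[str]]

    @property
    def headings(self) -> list[str]:
        return sorted(self.entries)

    def docs_with(self, heading: str) -> list[str]:
        try:
            return self.entries[heading]
        except KeyError:
            raise KeyError(f"heading {heading!r} absent from the inverted index") from None


class HeadingSimTable:
    """Symmetric precomputed heading-pair similarity table."""

    def __init__(self, pairs: dict[tuple[str, str], float]) -> None:
        self._pairs = {self._key(a, b): v for (a, b), v in pairs.items()}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def lookup(self, m: str, m2: str) -> float:
        try:
            return self._pairs[self._key(m, m2)]
        except KeyError:
            raise TableIncompleteError(f"heading pair ({m!r}, {m2!r}) not in table") from None

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        return self._pairs.items()

    def __len__(self) -> int:
        return len(self._pairs)


@dataclass
class OpCounters:
    """Instrumented operation counts for the complexity contract."""

    map_ops: int = 0      # heading-to-document best-match evaluations
    reduce_keys: int = 0  # distinct document pairs reduced


def count_operations(corpus: Corpus) -> OpCounters:
    """Analytic operation counts for a full engine run.

    The map stage evaluates each of the ``k`` vocabulary headings
    against each of the ``n`` documents exactly once; the reduce stage
    sees at most one key per unordered document pair.
    """
    k = len(corpus.heading_vocabulary())
    n = len(corpus)
    return OpCounters(map_ops=k * n, reduce_keys=n * (n - 1) // 2)


# -- stage 1: corpus inversion ----------------------------------------


def transform_corpus(corpus: Corpus) -> InvertedIndex:
    """Invert a corpus into ``heading -> [doc ids]``.

    Map emits one ``<heading, doc>`` pair per heading per document;
    shuffle groups by heading; reduce sorts each document list.
    """
    emitted = [(m, doc.doc_id) for doc in corpus for m in sorted(doc.headings)]
    grouped: dict[str, list[str]] = {}
    for heading, doc_id in emitted:
        grouped.setdefault(heading, []).append(doc_id)
    return InvertedIndex(entries={m: sorted(ds) for m, ds in sorted(grouped.items())})


# -- stage 2: heading-pair precompute ---------------------------------


def _headsim_partition(args: tuple) -> dict[tuple[str, str], float]:
    ontology, measure, pairs, children_mode = args
    return {
        (a, b): heading_sim(ontology, measure, a, b, children_mode) for a, b in pairs
    }


def _partitions(items: Sequence, workers: int) -> list[list]:
    """Round-robin split into ``workers`` partitions (some may be empty)."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    return [list(items[i::workers]) for i in range(workers)]


def _run_partitions(func, arg_list: list, processes: bool) -> list:
    if processes and len(arg_list) > 1:
        with ProcessPoolExecutor(max_workers=len(arg_list)) as pool:
            return list(pool.map(func, arg_list))
    return [func(args) for args in arg_list]


def precompute_heading_table(
    ontology: Ontology,
    measure: Measure | str,
    headings: Iterable[str],
    workers: int = 1,
    children_mode: str = "direct",
    processes: bool = False,
) -> HeadingSimTable:
    """All unordered heading-pair similarities, including self-pairs.

    The pair set is partitioned round-robin across ``workers``; the
    merged table is independent of the partitioning.
    """
    measure = Measure.from_name(measure)
    names = sorted(set(headings))
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i:]]
    results = _run_partitions(
        _headsim_partition,
        [(ontology, measure, part, children_mode) for part in _partitions(pairs, workers)],
        processes,
    )
    merged: dict[tuple[str, str], float] = {}
    for chunk in results:
        merged.update(chunk)
    return HeadingSimTable(merged)


# -- stage 3: document similarity -------------------------------------


def docsim_map(
    m: str,
    docs_with_m: Sequence[str],
    corpus: Corpus,
    table: HeadingSimTable,
    counters: OpCounters | None = None,
) -> list[tuple[PairKey, float]]:
    """Map one inverted-index entry to pair-keyed contributions.

    ``Sim(m, d')`` is evaluated once per target document ``d'`` and
    emitted toward every pair ``(d, d')`` with ``d`` containing ``m``.
    """
    out: list[tuple[PairKey, float]] = []
    for target in corpus:
        s = max(table.lookup(m, m2) for m2 in target.headings)
        if counters is not None:
            counters.map_ops += 1
        for doc_id in docs_with_m:
            if doc_id != target.doc_id:
                out.append((PairKey.of(doc_id, target.doc_id), s))
    return out


def combiner(pairs: Iterable[tuple[PairKey, float]]) -> list[tuple[PairKey, float]]:
    """Pre-shuffle partial aggregation: one summed value per key.

    Values are summed in sorted order; the per-key total is conserved,
    so reducing combined output equals reducing the raw emissions.
    """
    grouped: dict[PairKey, list[float]] = {}
    for key, value in pairs:
        grouped.setdefault(key, []).append(value)
    return [(key, sum(sorted(values))) for key, values in sorted(grouped.items())]


def shuffle(pairs: Iterable[tuple[PairKey, float]]) -> dict[PairKey, list[float]]:
    """Group emitted values by key, keys in sorted order."""
    grouped: dict[PairKey, list[float]] = {}
    for key, value in pairs:
        grouped.setdefault(key, []).append(value)
    return {key: grouped[key] for key in sorted(grouped)}


def docsim_reduce(key: PairKey, values: Sequence[float], corpus: Corpus) -> float:
    """AMM normalisation: summed contributions over ``|d| + |d'|``."""
    d, d2 = corpus[key.low], corpus[key.high]
    return sum(sorted(values)) / (d.mesh_number + d2.mesh_number)


def _map_partition(args: tuple) -> tuple[list[tuple[PairKey, float]], int]:
    headings, index_entries, corpus, table, use_combiner = args
    counters = OpCounters()
    emitted: list[tuple[PairKey, float]] = []
    for m in headings:
        emitted.extend(docsim_map(m, index_entries[m], corpus, table, counters))
    if use_combiner:
        emitted = combiner(emitted)
    return emitted, counters.map_ops


def run_docsim(
    ontology: Ontology,
    measure: Measure | str,
    corpus: Corpus,
    workers: int = 1,
    use_combiner: bool = False,
    table: HeadingSimTable | None = None,
    children_mode: str = "direct",
    processes: bool = False,
    counters: OpCounters | None = None,
    unit_diagonal: bool = True,
) -> DocSimMatrix:
    """Full engine run: invert, precompute, map, (combine,) shuffle, reduce.

    Output contract: elementwise equal (within 1e-9) to
    :func:`meshsim.aggregation.doc_sim_matrix_bruteforce` for any worker
    count and partitioning, with or without the combiner.
    """
    if len(corpus) == 0:
        raise CorpusError("corpus is empty")
    measure = Measure.from_name(measure)
    index = transform_corpus(corpus)
    if table is None:
        table = precompute_heading_table(
            ontology, measure, index.headings, workers, children_mode, processes
        )
    partitions = _partitions(index.headings, workers)
    results = _run_partitions(
        _map_partition,
        [(part, index.entries, corpus, table, use_combiner) for part in partitions],
        processes,
    )
    emitted: list[tuple[PairKey, float]] = []
    for chunk, ops in results:
        emitted.extend(chunk)
        if counters is not None:
            counters.map_ops += ops
    grouped = shuffle(emitted)
    if counters is not None:
        counters.reduce_keys = len(grouped)

    doc_ids = corpus.doc_ids
    position = {doc_id: i for i, doc_id in enumerate(doc_ids)}
    n = len(doc_ids)
    values = np.zeros((n, n), dtype=float)
    for key, contributions in grouped.items():
        s = docsim_reduce(key, contributions, corpus)
        i, j = position[key.low], position[key.high]
        values[i, j] = values[j, i] = s
    for i, doc_id in enumerate(doc_ids):
        doc = corpus[doc_id]
        values[i, i] = 1.0 if unit_diagonal else doc_sim(doc, doc, table)
    return DocSimMatrix(doc_ids=doc_ids, values=values)
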