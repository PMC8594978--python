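"""File dialects and the end-to-end pipeline.

Dialects (all UTF-8 plain text):

* corpus          — one document per line, ``docID#h1,h2,...``.  Heading
  names may themselves contain commas ("Genetic diseases, inborn"), so
  tokens are matched greedily longest-first against the registered
  heading vocabulary; a tab-separated heading list is also accepted.
* inverted index  — ``heading#doc1,doc2,...`` per line.
* heading table   — TSV ``headingA<TAB>headingB<TAB>similarity``.
* similarity matrix — TSV with a doc-id header row and column.
* labels          — TSV ``docID<TAB>label``.

:func:`run_pipeline` chains preprocessing, heading-table precompute,
the map/reduce document similarity engine, clustering, and (when true
labels are available) NMI scoring, writing every intermediate product.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .aggregation import Corpus, CorpusError, Document, DocSimMatrix
from .clustering import ClusterLabels, cluster, nmi
from .mapreduce import (
    HeadingSimTable,
    InvertedIndex,
    OpCounters,
    precompute_heading_table,
    run_docsim,
    transform_corpus,
)
from .ontology import Ontology, build_ontology, read_ontology_tsv

logger = logging.getLogger("meshsim")


class CorpusFormatError(CorpusError):
    """A corpus line could not be parsed; carries the line number."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


# -- corpus -----------------------------------------------------------


def _match_headings(headings_field: str, vocabulary: set[str], lineno: int) -> frozenset[str]:
    """Resolve a heading list, surviving commas inside heading names.

    Tab-separated fields are taken verbatim; otherwise comma tokens are
    rejoined greedily, longest candidate first, against the vocabulary.
    """
    if "\t" in headings_field:
        names = [t.strip() for t in headings_field.split("\t") if t.strip()]
        unknown = [n for n in names if n not in vocabulary]
        if unknown:
            raise CorpusFormatError(lineno, f"unknown headings {unknown!r}")
        return frozenset(names)
    tokens = headings_field.split(",")
    names: list[str] = []
    i = 0
    while i < len(tokens):
        for j in range(len(tokens), i, -1):
            candidate = ",".join(tokens[i:j]).strip()
            if candidate in vocabulary:
                names.append(candidate)
                i = j
                break
        else:
            raise CorpusFormatError(
                lineno, f"cannot resolve heading starting at {tokens[i].strip()!r}"
            )
    return frozenset(names)


def parse_corpus_lines(lines: Iterable[str], ontology: Ontology) -> Corpus:
    """Parse ``docID#h1,h2,...`` lines against a heading registry."""
    vocabulary = set(ontology.headings)
    documents: list[Document] = []
    seen: set[str] = set()
    n_lines = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        n_lines += 1
        if "#" not in line:
            raise CorpusFormatError(lineno, "missing '#' separator")
        doc_id, _, headings_field = line.partition("#")
        doc_id = doc_id.strip()
        if not doc_id:
            raise CorpusFormatError(lineno, "empty document id")
        if doc_id in seen:
            raise CorpusFormatError(lineno, f"duplicate document id {doc_id!r}")
        if not headings_field.strip():
            raise CorpusFormatError(lineno, "empty heading list")
        seen.add(doc_id)
        documents.append(
            Document(doc_id=doc_id, headings=_match_headings(headings_field, vocabulary, lineno))
        )
    if n_lines == 0:
        raise CorpusError("corpus is empty")
    return Corpus(documents)


def read_corpus(path: str | Path, ontology: Ontology) -> Corpus:
    with open(path, encoding="utf-8") as handle:
        return parse_corpus_lines(handle, ontology)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for doc in corpus:
            handle.write(f"{doc.doc_id}#{','.join(sorted(doc.headings))}\n")


# -- inverted index ---------------------------------------------------


def write_inverted_index(index: InvertedIndex, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for heading in index.headings:
            handle.write(f"{heading}#{','.join(index.entries[heading])}\n")


def read_inverted_index(path: str | Path) -> InvertedIndex:
    entries: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if "#" not in line:
                raise CorpusFormatError(lineno, "missing '#' separator")
            heading, _, docs = line.partition("#")
            entries[heading] = [d for d in docs.split(",") if d]
    return InvertedIndex(entries=entries)


# -- heading table ----------------------------------------------------


def write_heading_table(table: HeadingSimTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for (a, b), value in sorted(table.items()):
            handle.write(f"{a}\t{b}\t{value!r}\n")


def read_heading_table(path: str | Path) -> HeadingSimTable:
    pairs: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line:
                continue
            a, b, value = line.split("\t")
            pairs[(a, b)] = float(value)
    return HeadingSimTable(pairs)


# -- similarity matrix ------------------------------------------------


def write_matrix(matrix: DocSimMatrix, path: str | Path) -> None:
    """TSV with a doc-id header row and leading id column; full precision."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join([""] + matrix.doc_ids) + "\n")
        for doc_id, row in zip(matrix.doc_ids, matrix.values):
            handle.write("\t".join([doc_id] + [repr(float(v)) for v in row]) + "\n")


def read_matrix(path: str | Path) -> DocSimMatrix:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for raw in handle:
            fields = raw.rstrip("\n").split("\t")
            rows.append([float(v) for v in fields[1:]])
    return DocSimMatrix(doc_ids=header, values=np.asarray(rows))


# -- labels -----------------------------------------------------------


def write_labels(labels: dict[str, int] | ClusterLabels, path: str | Path) -> None:
    mapping = labels.as_dict() if isinstance(labels, ClusterLabels) else labels
    with open(path, "w", encoding="utf-8") as handle:
        for doc_id in sorted(mapping):
            handle.write(f"{doc_id}\t{mapping[doc_id]}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    labels: dict[str, int] = {}
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line:
                continue
            doc_id, label = line.split("\t")
            labels[doc_id] = int(label)
    return labels


# -- pipeline ---------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    ontology_path: str | Path
    corpus_path: str | Path
    out_dir: str | Path
    measure: str = "WP"
    workers: int = 1
    use_combiner: bool = False
    algorithm: str = "spectral"
    k: int = 2
    seed: int = 0
    labels_path: str | Path | None = None
    children_mode: str = "direct"
    res_normalization: bool = False
    processes: bool = False

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass
class PipelineResult:
    matrix: DocSimMatrix
    labels: ClusterLabels
    nmi: float | None
    counters: OpCounters
    stage_seconds: dict[str, float] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, ontology: Ontology | None = None) -> PipelineResult:
    """Preprocess, precompute, map/reduce, cluster, and (optionally) score.

    All intermediates (inverted index, heading table, matrix, predicted
    labels) are written under ``config.out_dir``.  With a labels file
    the NMI report is appended; without one clustering is still run and
    the score skipped with a warning.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def timed(stage: str, func, *args, **kwargs):
        start = time.perf_counter()
        result = func(*args, **kwargs)
        timings[stage] = time.perf_counter() - start
        logger.info("[%s] %.3fs", stage, timings[stage])
        return result

    if ontology is None:
        ontology = timed(
            "load-ontology", lambda: build_ontology(read_ontology_tsv(config.ontology_path))
        )
    corpus = timed("read-corpus", read_corpus, config.corpus_path, ontology)
    index = timed("index", transform_corpus, corpus)
    write_inverted_index(index, out_dir / "inverted_index.txt")
    table = timed(
        "heading-table",
        precompute_heading_table,
        ontology,
        config.measure,
        index.headings,
        config.workers,
        config.children_mode,
        config.processes,
    )
    write_heading_table(table, out_dir / "heading_table.tsv")
    counters = OpCounters()
    matrix = timed(
        "docsim",
        run_docsim,
        ontology,
        config.measure,
        corpus,
        config.workers,
        config.use_combiner,
        table,
        config.children_mode,
        config.processes,
        counters,
    )
    if config.res_normalization and matrix.values.max() > 1.0:
        off_diag = matrix.values.copy()
        np.fill_diagonal(off_diag, 0.0)
        peak = off_diag.max()
        if peak > 0:
            scaled = matrix.values / max(peak, 1.0)
            np.fill_diagonal(scaled, 1.0)
            matrix = DocSimMatrix(doc_ids=matrix.doc_ids, values=scaled)
    write_matrix(matrix, out_dir / "doc_similarity.tsv")
    logger.info("[docsim] map_ops=%d reduce_keys=%d", counters.map_ops, counters.reduce_keys)

    labels = timed("cluster", cluster, matrix, config.algorithm, config.k, config.seed)
    write_labels(labels, out_dir / "predicted_labels.tsv")

    score: float | None = None
    if config.labels_path is not None:
        true = read_labels(config.labels_path)
        missing = [d for d in labels.doc_ids if d not in true]
        if missing:
            raise CorpusError(f"label file does not cover documents {missing[:5]!r}...")
        score = timed(
            "nmi",
            nmi,
            [true[d] for d in labels.doc_ids],
            labels.labels,
        )
        (out_dir / "nmi.txt").write_text(f"{score!r}\n", encoding="utf-8")
    else:
        logger.warning("no label file given; NMI skipped")
    return PipelineResult(
        matrix=matrix, labels=labels, nmi=score, counters=counters, stage_seconds=timings
    )
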