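"""Map/shuffle/reduce engine: stage semantics, combiner, oracle equivalence."""

import numpy as np
import pytest

from meshsim import (
    Corpus,
    Document,
    OpCounters,
    PairKey,
    combiner,
    count_operations,
    doc_sim_matrix_bruteforce,
    docsim_map,
    docsim_reduce,
    precompute_heading_table,
    run_docsim,
    transform_corpus,
)
from meshsim.mapreduce import TableIncompleteError, shuffle

from conftest import random_fixture


def test_pairkey_canonical_and_no_self_pairs():
    assert PairKey.of("d2", "d1") == PairKey.of("d1", "d2") == PairKey("d1", "d2")
    with pytest.raises(ValueError):
        PairKey.of("d1", "d1")


class TestTransformCorpus:
    def test_grouping_example(self):
        corpus = Corpus(
            [
                Document("d1", frozenset({"m1", "m2"})),
                Document("d2", frozenset({"m1"})),
                Document("d4", frozenset({"m1", "m3"})),
            ]
        )
        index = transform_corpus(corpus)
        assert index.entries["m1"] == ["d1", "d2", "d4"]
        assert index.entries["m2"] == ["d1"]
        assert index.entries["m3"] == ["d4"]

    def test_single_doc_single_heading(self):
        index = transform_corpus(Corpus([Document("d", frozenset({"m"}))]))
        assert index.entries == {"m": ["d"]}

    def test_conservation_of_incidences(self):
        _, corpus, _ = random_fixture(11)
        index = transform_corpus(corpus)
        total_list_length = sum(len(docs) for docs in index.entries.values())
        assert total_list_length == sum(doc.mesh_number for doc in corpus)
        assert set().union(*index.entries.values()) == set(corpus.doc_ids)


class TestHeadingTable:
    def test_toy_table(self, toy):
        table = precompute_heading_table(toy, "WP", ["m1", "m2"])
        assert len(table) == 3  # (m1,m1), (m1,m2), (m2,m2)
        assert table.lookup("m1", "m2") == pytest.approx(0.5778, abs=1e-4)
        assert table.lookup("m2", "m1") == table.lookup("m1", "m2")

    def test_pair_count_combinatorics(self, toy):
        names = ["hA", "h1", "h2", "h11", "h12"]
        table = precompute_heading_table(toy, "WP", names)
        assert len(table) == len(names) * (len(names) + 1) // 2

    def test_partition_invariance(self, toy):
        names = sorted(toy.headings)
        tables = [
            dict(precompute_heading_table(toy, "Lin", names, workers=w).items())
            for w in (1, 2, 4)
        ]
        assert tables[0] == tables[1] == tables[2]

    def test_missing_pair_errors(self, toy):
        table = precompute_heading_table(toy, "WP", ["m1"])
        with pytest.raises(TableIncompleteError):
            table.lookup("m1", "m2")


class TestMapStage:
    def test_toy_emission(self, toy, toy_corpus):
        table = precompute_heading_table(toy, "WP", ["m1", "m2"])
        emitted = docsim_map("m1", ["d1"], toy_corpus, table)
        assert emitted == [(PairKey("d1", "d2"), pytest.approx(0.5778, abs=1e-4))]

    def test_all_docs_share_heading(self, toy):
        corpus = Corpus([Document(f"d{i}", frozenset({"m1"})) for i in range(4)])
        table = precompute_heading_table(toy, "WP", ["m1"])
        emitted = docsim_map("m1", corpus.doc_ids, corpus, table)
        assert len(emitted) == 4 * 3  # n(n-1) directed emissions
        assert len({key for key, _ in emitted}) == 6  # n(n-1)/2 canonical keys

    def test_single_document_emits_nothing(self, toy):
        corpus = Corpus([Document("d1", frozenset({"m1"}))])
        table = precompute_heading_table(toy, "WP", ["m1"])
        assert docsim_map("m1", ["d1"], corpus, table) == []

    def test_map_ops_counter_counts_targets_once(self, toy, toy_corpus):
        table = precompute_heading_table(toy, "WP", ["m1", "m2"])
        counters = OpCounters()
        docsim_map("m1", ["d1"], toy_corpus, table, counters)
        assert counters.map_ops == len(toy_corpus)


class TestCombinerAndReduce:
    def test_combiner_sums_per_key(self):
        k1, k2 = PairKey("a", "b"), PairKey("a", "c")
        out = combiner([(k1, 0.2), (k1, 0.3), (k2, 0.5)])
        assert out == [(k1, pytest.approx(0.5)), (k2, 0.5)]

    def test_combiner_empty_and_idempotent(self):
        assert combiner([]) == []
        pairs = [(PairKey("a", "b"), 0.25), (PairKey("a", "b"), 0.75), (PairKey("b", "c"), 1.0)]
        once = combiner(pairs)
        assert combiner(once) == once

    def test_combiner_conserves_per_key_sums(self):
        rng = np.random.default_rng(0)
        keys = [PairKey(f"d{i}", f"e{i}") for i in range(5)]
        pairs = [(keys[int(rng.integers(5))], float(rng.random())) for _ in range(200)]
        combined = dict(combiner(pairs))
        for key in keys:
            raw = sum(v for k, v in pairs if k == key)
            assert combined[key] == pytest.approx(raw, abs=1e-12)

    def test_reduce_normalisation_by_heading_counts(self):
        corpus = Corpus(
            [Document("d1", frozenset({"a", "b"})), Document("d2", frozenset({"x"}))]
        )
        value = docsim_reduce(PairKey("d1", "d2"), [0.6, 0.4, 0.5], corpus)
        assert value == pytest.approx(0.5)

    def test_reduce_all_ones_gives_one(self):
        corpus = Corpus(
            [Document("d1", frozenset({"a", "b", "c"})), Document("d2", frozenset({"x", "y"}))]
        )
        assert docsim_reduce(PairKey("d1", "d2"), [1.0] * 5, corpus) == pytest.approx(1.0)

    def test_shuffle_groups_and_sorts_keys(self):
        pairs = [(PairKey("b", "c"), 1.0), (PairKey("a", "b"), 2.0), (PairKey("a", "b"), 3.0)]
        grouped = shuffle(pairs)
        assert list(grouped) == [PairKey("a", "b"), PairKey("b", "c")]
        assert grouped[PairKey("a", "b")] == [2.0, 3.0]


class TestRunDocsim:
    def test_toy_matches_oracle(self, toy, toy_corpus):
        matrix = run_docsim(toy, "WP", toy_corpus)
        expected = doc_sim_matrix_bruteforce(toy, "WP", toy_corpus)
        np.testing.assert_allclose(matrix.values, expected.values, atol=1e-12)

    @pytest.mark.parametrize("measure", ["SP", "WP", "LC", "Res", "Lin", "Sch"])
    def test_oracle_equivalence_all_measures(self, measure):
        ontology, corpus, _ = random_fixture(21, max_docs=20, max_headings=15)
        expected = doc_sim_matrix_bruteforce(ontology, measure, corpus)
        matrix = run_docsim(ontology, measure, corpus, workers=3, use_combiner=True)
        np.testing.assert_allclose(matrix.values, expected.values, atol=1e-9)

    def test_worker_count_invariance_is_exact_without_combiner(self):
        ontology, corpus, _ = random_fixture(22, max_docs=30, max_headings=20)
        reference = run_docsim(ontology, "Lin", corpus, workers=1)
        for workers in (2, 4, 8):
            matrix = run_docsim(ontology, "Lin", corpus, workers=workers)
            np.testing.assert_array_equal(matrix.values, reference.values)

    def test_combiner_on_off_agree(self):
        ontology, corpus, _ = random_fixture(23, max_docs=25)
        off = run_docsim(ontology, "WP", corpus, workers=2, use_combiner=False)
        on = run_docsim(ontology, "WP", corpus, workers=2, use_combiner=True)
        np.testing.assert_allclose(on.values, off.values, atol=1e-9)

    def test_disjoint_documents_still_reduced(self, toy):
        # documents sharing no heading get |d| + |d2| contributions and a value
        corpus = Corpus(
            [Document("d1", frozenset({"h11"})), Document("d2", frozenset({"h2"}))]
        )
        counters = OpCounters()
        matrix = run_docsim(toy, "WP", corpus, counters=counters)
        assert counters.reduce_keys == 1
        expected = doc_sim_matrix_bruteforce(toy, "WP", corpus)
        np.testing.assert_allclose(matrix.values, expected.values, atol=1e-12)

    def test_process_pool_matches_serial(self, toy, toy_corpus):
        serial = run_docsim(toy, "WP", toy_corpus, workers=2)
        pooled = run_docsim(toy, "WP", toy_corpus, workers=2, processes=True)
        np.testing.assert_array_equal(serial.values, pooled.values)


class TestCounters:
    def test_analytic_counts(self):
        _, corpus, _ = random_fixture(31, max_docs=20)
        analytic = count_operations(corpus)
        k = len(corpus.heading_vocabulary())
        n = len(corpus)
        assert analytic.map_ops == k * n
        assert analytic.reduce_keys == n * (n - 1) // 2

    def test_instrumented_map_ops_match_kn(self):
        ontology, corpus, _ = random_fixture(32, max_docs=20)
        counters = OpCounters()
        run_docsim(ontology, "WP", corpus, workers=3, counters=counters)
        assert counters.map_ops == count_operations(corpus).map_ops
        assert counters.reduce_keys <= count_operations(corpus).reduce_keys

    def test_single_doc_has_no_reduce_keys(self, toy):
        corpus = Corpus([Document("d1", frozenset({"m1"}))])
        counters = OpCounters()
        run_docsim(toy, "WP", corpus, counters=counters)
        assert counters.reduce_keys == 0
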