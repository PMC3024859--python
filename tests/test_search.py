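"""Clique search: soundness, completeness, ordering, and the abstract variant."""

from itertools import combinations, product

import numpy as np
import pytest

from motifclique.oracle import exhaustive_cliques
from motifclique.reporting import format_clique_tsv, read_clique_tsv
from motifclique.search import (
    filter_candidates,
    find_cliques,
    find_cliques_abstract,
)
from motifclique.sequences import (
    InstanceTooShortError,
    MotifModel,
    SequenceSet,
    VertexRef,
)
from motifclique.simulate import generate_planted

from conftest import naive_hamming


def random_set(m, n, seed):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return SequenceSet(
        [(f"s{i}", "".join(rng.choice(bases, size=n))) for i in range(m)]
    )


class TestFindCliques:
    def test_identical_sequences_contain_all_aligned_tuples(self):
        S = SequenceSet([("a", "ACGTACG")] * 3)
        res = find_cliques(S, MotifModel(4, 1))
        aligned = {(j, j, j) for j in range(4)}
        assert aligned <= {c.starts for c in res.cliques}

    def test_every_output_clique_is_pairwise_within_2d(self):
        model = MotifModel(5, 1)
        S = random_set(4, 25, seed=3)
        res = find_cliques(S, model)
        for clique in res.cliques:
            for a, b in combinations(clique.strings, 2):
                assert naive_hamming(a, b) <= model.threshold

    def test_matches_exhaustive_product_space_oracle(self):
        model = MotifModel(5, 1)
        S = random_set(4, 20, seed=11)
        res = find_cliques(S, model)
        assert {c.starts for c in res.cliques} == exhaustive_cliques(S, model)

    def test_output_order_is_lexicographic_in_position_tuple(self):
        S = SequenceSet([("a", "ACGTACG")] * 3)
        res = find_cliques(S, MotifModel(4, 1))
        starts = [c.starts for c in res.cliques]
        assert starts == sorted(starts)

    def test_no_hidden_state_between_runs(self):
        model = MotifModel(5, 1)
        S = random_set(4, 20, seed=5)
        first = find_cliques(S, model)
        second = find_cliques(S, model)
        assert [c.starts for c in first.cliques] == [
            c.starts for c in second.cliques
        ]

    def test_empty_when_a_sequence_is_incompatible_with_sequence_0(self):
        S = SequenceSet([("a", "AAAAA"), ("b", "TTTTT")])
        res = find_cliques(S, MotifModel(5, 1))
        assert res.cliques == []
        assert res.complete

    def test_planted_tuple_is_found(self):
        model = MotifModel(7, 1)
        ds = generate_planted(5, 40, model, mode="exact_d", seed=9)
        res = find_cliques(ds.sequences, model)
        assert ds.planted_starts in {c.starts for c in res.cliques}

    def test_sequence_shorter_than_l_raises(self):
        S = SequenceSet([("a", "ACGTACGT"), ("b", "ACG")])
        with pytest.raises(InstanceTooShortError):
            find_cliques(S, MotifModel(5, 1))

    def test_first_k_truncates_and_flags_incomplete(self):
        S = SequenceSet([("a", "ACGTACG")] * 3)
        res = find_cliques(S, MotifModel(4, 1), max_cliques=2)
        assert len(res.cliques) == 2
        assert not res.complete

    def test_clique_members_carry_sequence_indices(self):
        S = SequenceSet([("a", "AAAAA"), ("b", "AAAAA")])
        res = find_cliques(S, MotifModel(5, 0))
        assert res.cliques[0].members == (VertexRef(0, 0), VertexRef(1, 0))


class TestFilterCandidates:
    def test_keeps_only_2d_neighbours_in_order_without_mutating_pool(self):
        model = MotifModel(4, 1)
        S = SequenceSet([("a", "AAAA"), ("b", "AAATGGGGTTAA")])
        pool = [VertexRef(1, j) for j in range(9)]
        kept = filter_candidates(S, model, VertexRef(0, 0), pool)
        strings = [S.lmer(v, 4) for v in kept]
        assert all(naive_hamming("AAAA", s) <= 2 for s in strings)
        assert kept == [v for v in pool if v in kept]  # order preserved
        assert len(pool) == 9

    def test_threshold_at_l_keeps_everything(self):
        model = MotifModel(4, 2)  # threshold 4 = l
        S = SequenceSet([("a", "AAAA"), ("b", "TTTTTT")])
        pool = [VertexRef(1, j) for j in range(3)]
        assert filter_candidates(S, model, VertexRef(0, 0), pool) == pool


class TestAbstractSearch:
    def test_always_true_predicate_yields_full_product(self):
        parts = [["a", "b"], ["c", "d"]]
        out = find_cliques_abstract(parts, lambda u, v: True)
        assert out == [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]

    def test_always_false_predicate_yields_nothing(self):
        out = find_cliques_abstract([["a"], ["b"], ["c"]], lambda u, v: False)
        assert out == []

    def test_asymmetric_predicate_is_rejected(self):
        def asym(u, v):
            return (u, v) == ("a", "b")

        with pytest.raises(ValueError, match="symmetric"):
            find_cliques_abstract([["a"], ["b"]], asym)

    def test_empty_part_is_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            find_cliques_abstract([["a"], []], lambda u, v: True)

    def test_agrees_with_product_space_filter_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            parts = [
                [f"{k}.{i}" for i in range(int(rng.integers(1, 5)))]
                for k in range(4)
            ]
            edges = set()
            all_labels = [x for p in parts for x in p]
            for u, v in combinations(all_labels, 2):
                if rng.random() < 0.5:
                    edges.add(frozenset((u, v)))

            def compatible(u, v):
                return frozenset((u, v)) in edges

            expected = [
                tup
                for tup in product(*parts)
                if all(
                    compatible(a, b) for a, b in combinations(tup, 2)
                )
            ]
            assert find_cliques_abstract(parts, compatible) == expected


class TestCliqueTsv:
    def test_tsv_layout_is_bit_exact(self):
        S = SequenceSet([("a", "AAAAA"), ("b", "AAAAA")])
        res = find_cliques(S, MotifModel(5, 0))
        assert format_clique_tsv(S, res) == (
            "clique\ta\tb\n"
            "0\ta:0:AAAAA\tb:0:AAAAA\n"
            "# cliques\t1\n"
        )

    def test_roundtrip(self, tmp_path):
        model = MotifModel(5, 1)
        S = random_set(3, 15, seed=2)
        res = find_cliques(S, model)
        path = tmp_path / "cliques.tsv"
        path.write_text(format_clique_tsv(S, res))
        ids, cliques = read_clique_tsv(path)
        assert ids == S.ids
        assert len(cliques) == len(res.cliques)
        for parsed, clique in zip(cliques, res.cliques):
            assert [
                (S.ids[v.seq_index], v.start, s)
                for v, s in zip(clique.members, clique.strings)
            ] == parsed
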