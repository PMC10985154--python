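"""The STP associative memory: storage, lazy columns, BEC association, export."""

import itertools
import json
from fractions import Fraction

import numpy as np
import pytest

from stpmem import (
    AssociativeMemory,
    RecognitionStatus,
    build_memory,
    encode_index,
    hamming,
    index_to_binary,
    index_to_bipolar,
)


def dense_oracle(n, stored_indices):
    """Brute-force L = sum_k e_{r_k} e_{r_k}^T as an explicit dense array."""
    size = 2**n
    L = np.zeros((size, size))
    for r in stored_indices:
        e = np.zeros(size)
        e[r - 1] = 1.0
        L += np.outer(e, e)
    return L


def oracle_learned_column(n, stored_indices, r_i, bec):
    """Independent inverse-distance column: loop over all stored patterns."""
    probe = index_to_binary(r_i, n)
    dist = {r: hamming(probe, index_to_binary(r, n)) for r in stored_indices}
    eligible = {r: s for r, s in dist.items() if 0 < s <= bec}
    if not eligible:
        return {}
    z = sum(Fraction(1, s) for s in eligible.values())
    return {r: Fraction(1, s) / z for r, s in eligible.items()}


class TestBuild:
    def test_example_storage_order(self, example_memory, example_indices):
        assert example_memory.stored == example_indices
        assert example_memory.m == 4 and example_memory.n == 5

    def test_empty_memory_is_zero_matrix(self):
        mem = AssociativeMemory([], n=3)
        assert mem.stored == ()
        assert np.array_equal(mem.dense_matrix(), np.zeros((8, 8)))

    def test_dense_equals_outer_product_sum(self):
        rng = np.random.default_rng(5)
        modes = [index_to_bipolar(int(r) + 1, 3) for r in rng.choice(8, 3, replace=False)]
        mem = build_memory(modes)
        assert np.array_equal(mem.dense_matrix(), dense_oracle(3, mem.stored))

    def test_duplicate_mode_names_pattern(self):
        with pytest.raises(ValueError, match=r"duplicate.*index 5"):
            AssociativeMemory([[1, 1, -1, 1, 1], [1, 1, -1, 1, 1]])

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            AssociativeMemory([[1, -1], [1, -1, 1]])


class TestColumn:
    def test_stored_column_is_point_mass(self, example_memory):
        assert example_memory.column(12) == {12: Fraction(1)}

    def test_unlearned_column_is_zero(self, example_memory):
        assert example_memory.column(21) == {}

    def test_learned_column_after_update(self, example_memory):
        example_memory.update_column(21)
        assert example_memory.column(21) == {
            5: Fraction(2, 5),
            19: Fraction(1, 5),
            29: Fraction(2, 5),
        }

    def test_out_of_range(self, example_memory):
        with pytest.raises(ValueError):
            example_memory.column(33)


class TestUpdateColumn:
    def test_example_distances_and_probabilities(self, example_memory, example_probe):
        assert example_memory.distances(example_probe) == [1, 5, 2, 1]
        col = example_memory.update_column(21)
        assert col == {5: Fraction(2, 5), 19: Fraction(1, 5), 29: Fraction(2, 5)}
        assert [float(col[r]) for r in (5, 19, 29)] == [0.4, 0.2, 0.4]

    def test_bec_zero_window_is_empty(self, example_modes):
        mem = AssociativeMemory(example_modes, bec=0)
        assert mem.update_column(21) == {}
        assert 21 not in mem.learned  # rejected probes are never cached

    def test_bec_n_matches_brute_force(self, example_modes):
        mem = AssociativeMemory(example_modes, bec=5)
        for r_i in (1, 2, 21, 32):
            assert mem.update_column(r_i) == oracle_learned_column(
                5, mem.stored, r_i, 5
            )

    def test_stored_index_refused(self, example_memory):
        with pytest.raises(ValueError, match="stored"):
            example_memory.update_column(12)

    def test_inverse_distance_law_and_monotonicity(self, example_memory):
        col = example_memory.update_column(21)
        probe = index_to_binary(21, 5)
        products = {
            col[r] * hamming(probe, index_to_binary(r, 5)) for r in col
        }
        assert len(products) == 1  # probability x distance constant
        dists = {r: hamming(probe, index_to_binary(r, 5)) for r in col}
        for r, s in itertools.combinations(col, 2):
            if dists[r] < dists[s]:
                assert col[r] > col[s]


class TestRecognize:
    def test_stored_mode_exact(self, example_memory, example_modes):
        res = example_memory.recognize(example_modes[1])
        assert res.status is RecognitionStatus.RECOGNIZED_EXACT
        assert res.distribution == {12: Fraction(1)} and res.query_index == 12

    def test_association_with_distribution(self, example_memory, example_probe):
        res = example_memory.recognize(example_probe)
        assert res.status is RecognitionStatus.CLASSIFIED_BY_ASSOCIATION
        assert res.probabilities() == {5: 0.4, 19: 0.2, 29: 0.4}

    def test_far_probe_rejected(self, example_modes):
        mem = AssociativeMemory(example_modes, bec=1)
        probe = -np.ones(5, dtype=np.int8)  # min distance 2 from the stored set
        assert all(d > 1 for d in mem.distances(probe))
        res = mem.recognize(probe)
        assert res.status is RecognitionStatus.REJECTED and res.distribution == {}

    def test_second_query_uses_cache(self, example_memory, example_probe):
        first = example_memory.recognize(example_probe)
        second = example_memory.recognize(example_probe)
        assert second.status is RecognitionStatus.CLASSIFIED_BY_ASSOCIATION
        assert second.distribution == first.distribution


class TestClassifySample:
    def test_point_mass_is_seed_independent(self, example_memory, example_modes):
        res = example_memory.recognize(example_modes[0])
        assert {example_memory.classify_sample(res, seed=s) for s in range(5)} == {5}

    def test_same_seed_same_draw(self, example_memory, example_probe):
        res = example_memory.recognize(example_probe)
        draws = [example_memory.classify_sample(res, seed=42) for _ in range(3)]
        assert len(set(draws)) == 1

    def test_empirical_frequencies(self, example_memory, example_probe):
        res = example_memory.recognize(example_probe)
        rng = np.random.default_rng(7)
        seeds = rng.integers(0, 2**31, size=20000)
        counts = {5: 0, 19: 0, 29: 0}
        for s in seeds:
            counts[example_memory.classify_sample(res, seed=int(s))] += 1
        n = len(seeds)
        for r, p in ((5, 0.4), (19, 0.2), (29, 0.4)):
            sigma = (p * (1 - p) / n) ** 0.5
            assert abs(counts[r] / n - p) < 3 * sigma

    def test_rejected_result_raises(self, example_modes):
        mem = AssociativeMemory(example_modes, bec=0)
        res = mem.recognize(-np.asarray(example_modes[0]))
        with pytest.raises(ValueError):
            mem.classify_sample(res, seed=0)


class TestLearnAll:
    def test_column_21_and_self_point_masses(self, example_memory):
        table = example_memory.learn_all()
        assert table[21] == {5: Fraction(2, 5), 19: Fraction(1, 5), 29: Fraction(2, 5)}
        for r in example_memory.stored:
            assert table[r] == {r: Fraction(1)}

    def test_rejected_count_matches_distance_scan(self, example_memory):
        table = example_memory.learn_all()
        empty = sum(1 for col in table.values() if not col)
        far = sum(
            1
            for r in range(1, 33)
            if min(
                hamming(index_to_binary(r, 5), index_to_binary(s, 5))
                for s in example_memory.stored
            )
            > 2
        )
        assert empty == far

    def test_cap_enforced(self):
        mem = AssociativeMemory([], n=17)
        with pytest.raises(ValueError, match="cap"):
            mem.learn_all(cap=16)


class TestDenseOracleAgreement:
    def test_structure_before_updates(self, example_memory, example_indices):
        L = example_memory.dense_matrix()
        assert set(np.unique(L)) <= {0.0, 1.0}
        assert np.array_equal(L, np.diag(np.diag(L)))
        assert np.trace(L) == 4
        assert {i + 1 for i in np.flatnonzero(np.diag(L))} == set(example_indices)
        assert np.array_equal(L @ L, L)  # idempotent 0/1 diagonal

    @pytest.mark.parametrize("trial", range(3))
    def test_sparse_columns_match_dense(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 7))
        m = int(rng.integers(1, 2**n // 2))
        stored = [int(r) + 1 for r in rng.choice(2**n, m, replace=False)]
        mem = AssociativeMemory.from_indices(n, stored, bec=2)
        # learn a few random columns, then compare every column against the
        # dense matrix assembled independently
        for r_i in rng.choice(2**n, 5):
            r_i = int(r_i) + 1
            if r_i not in mem.stored:
                mem.update_column(r_i)
        L = dense_oracle(n, stored)
        for r_i, col in mem.learned.items():
            for r_k, p in col.items():
                L[r_k - 1, r_i - 1] = float(p)
        for r in range(1, 2**n + 1):
            sparse = {k: float(v) for k, v in mem.column(r).items()}
            dense_col = {
                i + 1: L[i, r - 1] for i in np.flatnonzero(L[:, r - 1])
            }
            assert sparse == pytest.approx(dense_col)

    def test_dense_cap(self):
        mem = AssociativeMemory([], n=9)
        with pytest.raises(ValueError):
            mem.dense_matrix(cap=8)


class TestMutationAndCache:
    def test_add_mode_clears_learned(self, example_memory, example_probe):
        example_memory.recognize(example_probe)
        assert example_memory.learned
        example_memory.add_mode([1, 1, 1, 1, 1])
        assert not example_memory.learned

    def test_remove_mode_clears_learned(self, example_memory, example_probe):
        example_memory.recognize(example_probe)
        example_memory.remove_mode(12)
        assert not example_memory.learned and 12 not in example_memory.stored

    def test_bec_setter_clears_cache(self, example_memory, example_probe):
        example_memory.recognize(example_probe)
        example_memory.bec = 3
        assert not example_memory.learned

    def test_bec_increase_reconsiders_rejected(self, example_modes):
        mem = AssociativeMemory(example_modes, bec=0)
        probe = [-1, 1, -1, 1, 1]
        assert mem.recognize(probe).status is RecognitionStatus.REJECTED
        mem.bec = 2
        assert (
            mem.recognize(probe).status
            is RecognitionStatus.CLASSIFIED_BY_ASSOCIATION
        )


class TestSerialization:
    def test_json_roundtrip_exact(self, example_memory, example_probe):
        example_memory.recognize(example_probe)
        text = example_memory.to_json()
        doc = json.loads(text)
        assert doc["stored"] == [5, 12, 19, 29] and doc["bec"] == 2
        assert doc["learned"]["21"]["5"] == "2/5"
        clone = AssociativeMemory.from_json(text)
        assert clone.stored == example_memory.stored
        assert clone.learned == example_memory.learned
        assert clone.bec == example_memory.bec

    def test_rejects_inconsistent_learned_column(self):
        bad = json.dumps(
            {"n": 3, "bec": 1, "stored": [1], "learned": {"2": {"7": "1/1"}}}
        )
        with pytest.raises(ValueError, match="non-stored"):
            AssociativeMemory.from_json(bad)


class TestTransitionExport:
    def test_graph_edges_and_weights(self, example_memory, example_probe):
        example_memory.recognize(example_probe)
        g = example_memory.transition_graph()
        assert g[21][5]["probability"] == 0.4
        assert g[21][19]["rational"] == "1/5"
        for r in example_memory.stored:
            assert g[r][r]["probability"] == 1.0

    def test_dot_and_tsv_outputs(self, example_memory, example_probe):
        example_memory.recognize(example_probe)
        dot = example_memory.to_dot()
        assert dot.startswith("digraph L {") and '21 -> 5 [label="2/5"]' in dot
        table = example_memory.edge_table()
        row = table[(table.source == 21) & (table.target == 29)].iloc[0]
        assert row.probability == 0.4 and row.rational == "2/5"


class TestFullCapacity:
    def test_all_modes_of_small_space_exactly_recalled(self):
        n = 6
        mem = AssociativeMemory.from_indices(n, range(1, 2**n + 1), bec=0)
        for r in range(1, 2**n + 1):
            res = mem.recognize(index_to_bipolar(r, n))
            assert res.status is RecognitionStatus.RECOGNIZED_EXACT
            assert res.distribution == {r: Fraction(1)}
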