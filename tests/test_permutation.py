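import itertools
import math

import numpy as np
import pytest

from genescreen import (
    ClassVector,
    PermutationEnsemble,
    combination_count,
    enumerate_labelings,
    exceedance_counts,
    exhaustive_ensemble,
    generate_null_labels,
    null_count_table,
    right_quantile,
    snr_scores,
)
from genescreen.permutation import null_score_matrix, table_from_score_matrix

GRID = np.round(np.arange(0.1, 0.65, 0.1), 10)


class TestCombinationCount:
    def test_randomization_space_of_a_27_11_split(self):
        assert combination_count(27, 11) == 1_203_322_288

    def test_matches_math_comb_generally(self):
        assert combination_count(5, 5) == math.comb(10, 5)


class TestGenerateNullLabels:
    def test_class_sizes_preserved_for_500_draws_on_27_11(self):
        labels = ClassVector(np.array([1] * 27 + [0] * 11))
        ens = generate_null_labels(labels, B=500, seed=42)
        assert ens.perms.shape == (500, 38)
        np.testing.assert_array_equal(ens.perms.sum(axis=1), np.full(500, 27))

    def test_same_seed_reproduces_the_ensemble(self):
        labels = ClassVector(np.array([1, 1, 0, 0, 1]))
        a = generate_null_labels(labels, B=50, seed=7)
        b = generate_null_labels(labels, B=50, seed=7)
        np.testing.assert_array_equal(a.perms, b.perms)

    def test_draws_are_uniform_over_the_arrangement_space(self):
        # 2/2 split: 6 distinct arrangements, each with probability 1/6
        labels = ClassVector(np.array([1, 1, 0, 0]))
        ens = generate_null_labels(labels, B=6000, seed=3)
        keys = [tuple(row) for row in ens.perms]
        distinct = set(map(tuple, enumerate_labelings(labels)))
        assert set(keys) == distinct
        p = 1 / 6
        se = math.sqrt(p * (1 - p) / 6000)
        for arrangement in distinct:
            freq = keys.count(arrangement) / 6000
            assert abs(freq - p) < 5 * se

    def test_nonpositive_b_rejected(self):
        labels = ClassVector(np.array([1, 1, 0, 0]))
        with pytest.raises(ValueError):
            generate_null_labels(labels, B=0, seed=1)


class TestEnumeration:
    def test_enumerates_all_distinct_arrangements(self):
        labels = ClassVector(np.array([1, 1, 1, 0, 0, 0]))
        all_perms = enumerate_labelings(labels)
        assert all_perms.shape == (math.comb(6, 3), 6)
        assert len(set(map(tuple, all_perms))) == math.comb(6, 3)
        np.testing.assert_array_equal(all_perms.sum(axis=1), np.full(20, 3))

    def test_refuses_non_toy_sample_sizes(self):
        labels = ClassVector(np.array([1] * 10 + [0] * 10))
        with pytest.raises(ValueError, match="m <= 12"):
            enumerate_labelings(labels)


class TestExceedanceCounts:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.5, (2, 0)), (0.3, (2, 1)), (0.55, (2, 0)), (0.6, (1, 0))],
    )
    def test_inclusive_tail_counts(self, r, expected):
        scores = np.array([0.6, -0.3, 0.2, 0.55])
        assert exceedance_counts(scores, r) == expected

    def test_all_zero_scores_count_nothing(self):
        assert exceedance_counts(np.zeros(10), 0.2) == (0, 0)

    def test_sentinels_count_on_their_sign_side(self):
        scores = np.array([np.inf, -np.inf, 0.0])
        assert exceedance_counts(scores, 100.0) == (1, 1)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            exceedance_counts(np.array([1.0]), 0.0)


class TestRightQuantile:
    def test_fifth_largest_of_1_to_100(self):
        values = np.arange(1, 101)
        assert right_quantile(values, 0.05) == 96

    def test_25th_largest_of_1_to_500(self):
        values = np.random.default_rng(0).permutation(np.arange(1, 501))
        assert right_quantile(values, 0.05) == 476

    def test_constant_sample_returns_the_constant(self):
        assert right_quantile(np.full(37, 7.0), 0.31) == 7.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            right_quantile(np.array([]), 0.05)


class TestNullCountTable:
    def test_two_hand_chosen_permutations_on_a_toy_matrix(self):
        values = np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
                [1.0, 3.0, 2.0, 4.0, 2.0, 3.0],
            ]
        )
        perms = np.array([[1, 1, 1, 0, 0, 0], [0, 1, 0, 1, 0, 1]])
        ens = PermutationEnsemble(perms, seed=None)
        grid = np.array([0.5, 1.0])
        table = null_count_table(values, ens, grid, alpha=0.5)
        for j in range(2):
            scores = snr_scores(values, perms[j]).scores
            for k, r in enumerate(grid):
                assert table.counts_pos[j, k] == np.sum(scores >= r)
                assert table.counts_neg[j, k] == np.sum(scores <= -r)

    def test_constant_matrix_gives_zero_counts_and_envelopes(self):
        values = np.full((4, 6), 2.5)
        labels = ClassVector(np.array([1, 1, 1, 0, 0, 0]))
        ens = generate_null_labels(labels, B=10, seed=0)
        table = null_count_table(values, ens, GRID)
        assert not table.counts_pos.any() and not table.counts_neg.any()
        assert not table.l1.any() and not table.l2.any()

    def test_rows_nonincreasing_along_the_grid(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(30, 10))
        labels = ClassVector(np.array([1] * 5 + [0] * 5))
        table = null_count_table(values, generate_null_labels(labels, 25, 1), GRID)
        assert (np.diff(table.counts_pos, axis=1) <= 0).all()
        assert (np.diff(table.counts_neg, axis=1) <= 0).all()
        assert (np.diff(table.l1) <= 0).all() and (np.diff(table.l2) <= 0).all()

    def test_label_swap_exchanges_the_two_tails(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(20, 8))
        labels = ClassVector(np.array([1] * 4 + [0] * 4))
        ens = generate_null_labels(labels, B=15, seed=2)
        swapped = PermutationEnsemble(1 - ens.perms, seed=None)
        t1 = null_count_table(values, ens, GRID)
        t2 = null_count_table(values, swapped, GRID)
        np.testing.assert_array_equal(t1.counts_pos, t2.counts_neg)
        np.testing.assert_array_equal(t1.counts_neg, t2.counts_pos)

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(6, 6))
        labels = ClassVector(np.array([1, 1, 1, 0, 0, 0]))
        ens = generate_null_labels(labels, B=20, seed=4)
        table = null_count_table(values, ens, GRID)
        from test_snr import naive_scores

        for j, k in itertools.product(range(20), range(GRID.size)):
            s = naive_scores(values, ens.perms[j])
            n1 = sum(1 for x in s if x >= GRID[k])
            n2 = sum(1 for x in s if x <= -GRID[k])
            assert table.counts_pos[j, k] == n1
            assert table.counts_neg[j, k] == n2
        # ceil(0.05 * 20) = 1: the envelope is the largest of the 20 counts
        for k in range(GRID.size):
            assert table.l1[k] == max(table.counts_pos[:, k])
            assert table.l2[k] == max(table.counts_neg[:, k])

    def test_retained_score_matrix_reproduces_the_streamed_table(self):
        rng = np.random.default_rng(21)
        values = rng.normal(size=(15, 8))
        labels = ClassVector(np.array([1] * 4 + [0] * 4))
        ens = generate_null_labels(labels, B=12, seed=9)
        streamed = null_count_table(values, ens, GRID)
        retained = table_from_score_matrix(null_score_matrix(values, ens), GRID)
        np.testing.assert_array_equal(streamed.counts_pos, retained.counts_pos)
        np.testing.assert_array_equal(streamed.counts_neg, retained.counts_neg)
        np.testing.assert_array_equal(streamed.l1, retained.l1)
        np.testing.assert_array_equal(streamed.l2, retained.l2)

    def test_exhaustive_ensemble_feeds_the_table(self):
        rng = np.random.default_rng(31)
        values = rng.normal(size=(10, 6))
        labels = ClassVector(np.array([1, 1, 1, 0, 0, 0]))
        table = null_count_table(values, exhaustive_ensemble(labels), GRID)
        assert table.counts_pos.shape == (20, GRID.size)
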