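import numpy as np
import pytest

from genescreen import (
    CountCurvePair,
    NoCrossingError,
    combine_threshold,
    exceedance_counts,
    observed_count_curve,
    select_genes,
    snr_scores,
)
from genescreen.threshold import curve_intersection
from genescreen.worked_example import (
    leukemia_threshold,
    negative_tail_curve,
    positive_tail_curve,
)


class TestCurveIntersection:
    def test_published_positive_tail_reads_0_44(self):
        """Interpolating the published N1/L1 columns lands on r0 = 0.44."""
        r0 = curve_intersection(positive_tail_curve())
        assert r0 == pytest.approx(0.4 + 0.1 * 128 / 317, abs=1e-12)
        assert round(r0, 2) == 0.44

    def test_published_negative_tail_near_minus_0_5(self):
        # the published figure reading is -0.49; interpolation of the same
        # printed columns gives -0.497, on the same grid interval
        t0 = -curve_intersection(negative_tail_curve())
        assert t0 == pytest.approx(-(0.4 + 0.1 * 264 / 271), abs=1e-12)
        assert 0.4 < abs(t0) < 0.5

    def test_symmetric_crossing_returns_midpoint(self):
        pair = CountCurvePair(
            np.array([0.2, 0.4]), np.array([20, 10]), np.array([30, 0]), "positive"
        )
        assert curve_intersection(pair) == pytest.approx(0.3)

    def test_exact_zero_difference_returns_the_grid_point(self):
        pair = CountCurvePair(
            np.array([0.1, 0.2, 0.3]),
            np.array([50, 30, 20]),
            np.array([60, 30, 10]),
            "positive",
        )
        assert curve_intersection(pair) == pytest.approx(0.2)

    def test_always_positive_difference_is_an_error(self):
        pair = CountCurvePair(
            np.array([0.1, 0.2]), np.array([31, 21]), np.array([30, 20]), "positive"
        )
        with pytest.raises(NoCrossingError, match="refine"):
            curve_intersection(pair)

    def test_multiple_crossings_warn_and_return_the_first(self):
        pair = CountCurvePair(
            np.array([0.1, 0.2, 0.3, 0.4]),
            np.array([40, 30, 10, 8]),
            np.array([50, 20, 20, 0]),
            "positive",
        )
        with pytest.warns(UserWarning, match="multiple"):
            first = curve_intersection(pair)
        assert 0.1 < first < 0.2

    def test_abscissa_lies_inside_the_bracketing_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            obs = np.sort(rng.integers(0, 100, 6))[::-1]
            null = np.sort(rng.integers(0, 100, 6))[::-1]
            grid = np.round(np.arange(0.1, 0.65, 0.1), 10)
            pair = CountCurvePair(grid, obs, null, "positive")
            d = obs.astype(float) - null
            try:
                x = curve_intersection(pair)
            except NoCrossingError:
                assert not ((d[:-1] < 0) & (d[1:] > 0)).any() and not (d == 0).any()
                continue
            assert grid[0] <= x <= grid[-1]


class TestCombineThreshold:
    def test_published_pair_gives_0_49(self):
        res = combine_threshold(0.44, -0.49, 0.0)
        assert res.r_star == pytest.approx(0.49)
        assert res.t0 == -0.49

    def test_equal_tails(self):
        assert combine_threshold(0.3, -0.3).r_star == pytest.approx(0.3)

    def test_adjustment_is_added(self):
        assert combine_threshold(0.44, -0.49, 0.01).r_star == pytest.approx(0.50)

    def test_negative_adjustment_rejected(self):
        with pytest.raises(ValueError):
            combine_threshold(0.44, -0.49, -0.1)

    def test_worked_example_rounds_to_half(self):
        d = leukemia_threshold()
        assert d["rounded"].r0 == 0.44
        assert d["rounded"].r_star == 0.5


class TestSelectGenes:
    def test_threshold_application_with_directions(self):
        scores = np.array([0.6, -0.3, 0.2, -0.55])
        sel = select_genes(scores, ["g1", "g2", "g3", "g4"], 0.5)
        assert sel.gene_ids == ("g1", "g4")
        np.testing.assert_array_equal(sel.directions, [1, -1])

    def test_threshold_above_all_scores_selects_nothing(self):
        sel = select_genes(np.array([0.2, -0.1]), ["a", "b"], 0.9)
        assert len(sel) == 0

    def test_size_identity_with_tail_counts(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(scale=0.5, size=400)
        for r in (0.1, 0.25, 0.5):
            n1, n2 = exceedance_counts(scores, r)
            sel = select_genes(scores, [f"g{i}" for i in range(400)], r)
            assert len(sel) == n1 + n2

    def test_selection_grows_as_the_threshold_shrinks(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=300)
        ids = [f"g{i}" for i in range(300)]
        tight = set(select_genes(scores, ids, 0.8).gene_ids)
        loose = set(select_genes(scores, ids, 0.4).gene_ids)
        assert tight <= loose


class TestObservedCurve:
    def test_negating_scores_swaps_the_tails(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=100)
        grid = np.array([0.2, 0.4, 0.6])
        pos = observed_count_curve(scores, grid, "positive")
        neg = observed_count_curve(-scores, grid, "negative")
        np.testing.assert_array_equal(pos.observed, neg.observed)

    def test_zero_scores_give_zero_curve(self):
        curve = observed_count_curve(np.zeros(50), np.array([0.1, 0.2]), "positive")
        assert not curve.observed.any()

    def test_monotonicity_validation_rejects_rising_counts(self):
        with pytest.raises(ValueError, match="nonincreasing"):
            CountCurvePair(
                np.array([0.1, 0.2]), np.array([5, 9]), np.array([7, 3]), "positive"
            )


class TestGridRefinementStability:
    def test_halving_the_step_moves_the_abscissa_at_most_one_coarse_step(self):
        from genescreen import generate_null_labels, null_count_table
        from genescreen.simulate import SimulationSpec, simulate

        matrix, labels, _ = simulate(
            SimulationSpec(n_genes=800, n_informative=80, effect=1.5, seed=14)
        )
        scores = snr_scores(matrix.values, labels).scores
        ens = generate_null_labels(labels, B=200, seed=5)
        coarse_grid = np.round(np.arange(0.1, 0.65, 0.1), 10)
        fine_grid = np.round(np.arange(0.1, 0.625, 0.05), 10)
        coarse = null_count_table(matrix.values, ens, coarse_grid)
        fine = null_count_table(matrix.values, ens, fine_grid)
        r0_coarse = curve_intersection(
            observed_count_curve(scores, coarse_grid, "positive", coarse.l1)
        )
        r0_fine = curve_intersection(
            observed_count_curve(scores, fine_grid, "positive", fine.l1)
        )
        assert abs(r0_coarse - r0_fine) <= 0.1
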