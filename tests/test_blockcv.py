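import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from kelpshift.blockcv import (
    assign_folds,
    auc,
    choose_block_size,
    cross_validate,
    ensemble_map,
    make_folds_with_presences,
    select_candidate,
    tss,
)
from kelpshift.grid import GridSpec


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([0.5, 0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_enumerated_example(self):
        # four presence/background pairs: three wins, one loss -> 0.75
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestTss:
    def test_perfect_separation(self):
        assert tss([True, True, False, False], [1, 1, 0, 0]) == 1.0

    def test_everything_suitable_scores_zero(self):
        assert tss([True, True, True], [1, 0, 0]) == 0.0

    def test_arithmetic(self):
        # sensitivity 0.95, specificity 0.66
        pred = np.r_[np.ones(95), np.zeros(5), np.zeros(66), np.ones(34)].astype(bool)
        y = np.r_[np.ones(100), np.zeros(100)]
        assert tss(pred, y) == pytest.approx(0.61)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            tss([True, False], [1, 1])


class TestChooseBlockSize:
    grid = GridSpec(0.0, 5.0, 50.0, 55.0, 0.05)  # 100 x 100

    def test_white_field_picks_smallest_candidate(self, rng):
        layer = rng.normal(size=self.grid.shape)
        chosen = choose_block_size(layer, self.grid, [0.25, 0.5, 1.0, 2.0], seed=0)
        assert chosen == 0.25

    def test_smoothed_field_needs_blocks_at_least_smoothing_scale(self, rng):
        L = 0.5  # degrees; 10 cells
        layer = gaussian_filter(rng.normal(size=self.grid.shape), sigma=L / self.grid.resolution)
        chosen = choose_block_size(layer, self.grid, [0.1, 0.25, 0.5, 1.0, 2.0, 4.0], seed=0)
        assert chosen >= L

    def test_single_candidate_returned(self, rng):
        layer = rng.normal(size=self.grid.shape)
        assert choose_block_size(layer, self.grid, [0.7], seed=0) == 0.7

    def test_too_few_valid_cells_errors(self, rng):
        layer = np.full(self.grid.shape, np.nan)
        layer[:5, :5] = rng.normal(size=(5, 5))
        with pytest.raises(ValueError, match="100 valid cells"):
            choose_block_size(layer, self.grid, [0.25, 0.5], seed=0)


class TestAssignFolds:
    grid = GridSpec(0.0, 1.0, 50.0, 51.0, 0.05)  # 20 x 20

    def test_round_robin_balances_blocks(self):
        mask = np.ones(self.grid.shape, dtype=bool)
        folds = assign_folds(self.grid, mask, block_size_deg=0.2, k=5, seed=0)  # 25 blocks
        blocks_per_fold = [
            np.unique(folds.block_grid[folds.fold_grid == f]).size for f in range(1, 6)
        ]
        assert blocks_per_fold == [5, 5, 5, 5, 5]

    def test_single_block_cannot_fill_folds(self):
        mask = np.ones(self.grid.shape, dtype=bool)
        with pytest.raises(ValueError, match="cannot fill"):
            assign_folds(self.grid, mask, block_size_deg=1.0, k=5, seed=0)

    def test_same_seed_same_assignment(self):
        mask = np.ones(self.grid.shape, dtype=bool)
        a = assign_folds(self.grid, mask, 0.2, k=5, seed=3)
        b = assign_folds(self.grid, mask, 0.2, k=5, seed=3)
        np.testing.assert_array_equal(a.fold_grid, b.fold_grid)

    def test_no_block_split_across_folds(self):
        mask = np.ones(self.grid.shape, dtype=bool)
        folds = assign_folds(self.grid, mask, 0.25, k=4, seed=1)
        for b in np.unique(folds.block_grid):
            cells = folds.fold_grid[(folds.block_grid == b) & mask]
            assert np.unique(cells).size == 1

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(self.grid, np.ones(self.grid.shape, bool), 0.2, k=1, seed=0)


class TestSelectCandidate:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["classes", "multiplier", "n_classes", "mean_auc_train", "mean_auc_test"])

    def test_single_candidate_chosen(self):
        t = self._table([("lqp", 1.0, 3, 0.9, 0.8)])
        assert select_candidate(t) == ("lqp", 1.0)

    def test_smaller_gap_wins_despite_lower_test_auc(self):
        t = self._table([("lqp", 1.0, 3, 0.95, 0.85), ("lq", 1.0, 2, 0.90, 0.88)])
        assert select_candidate(t) == ("lq", 1.0)  # gap 0.02 < 0.10

    def test_ties_resolve_to_higher_test_auc_then_fewer_classes(self):
        t = self._table([("lqp", 1.0, 3, 0.92, 0.90), ("l", 1.0, 1, 0.92, 0.90), ("lq", 1.0, 2, 0.90, 0.88)])
        assert select_candidate(t) == ("l", 1.0)


@pytest.fixture(scope="module")
def cv_setup(small_world):
    from kelpshift.stack import apply_masks
    from kelpshift.synthetic import sample_occurrences
    from kelpshift.occurrences import OccurrenceSet, grid_occurrences

    stack = apply_masks(small_world.present, small_world.depth).select(["sst_max", "salinity"])
    occ = sample_occurrences(small_world, 300, seed=1)
    presences = grid_occurrences(OccurrenceSet("kelp", occ), small_world.grid, mask=stack.mask)
    folds = make_folds_with_presences(small_world.grid, stack.mask, presences, 0.5, k=4, seed=0)
    return stack, presences, folds


class TestCrossValidate:

    def test_single_candidate_is_chosen_and_maps_average(self, cv_setup):
        stack, presences, folds = cv_setup
        cv = cross_validate(presences, stack, folds, candidates=[("lq", 1.0)], seed=0)
        assert cv.chosen == ("lq", 1.0)
        assert len(cv.fits) == folds.k
        # averaged map equals the mean of sub-model maps cell-wise
        maps = [ensemble_map([f], stack) for f in cv.fits]
        np.testing.assert_allclose(cv.mean_map, np.mean(maps, axis=0), atol=1e-12)

    def test_every_presence_cell_has_exactly_one_fold(self, cv_setup):
        stack, presences, folds = cv_setup
        pres_fold = folds.fold_of_cells(presences.rows, presences.cols)
        assert np.all((pres_fold >= 1) & (pres_fold <= folds.k))
        assert np.unique(pres_fold).size == folds.k  # every fold holds presences

    def test_metrics_within_bounds(self, cv_setup):
        stack, presences, folds = cv_setup
        cv = cross_validate(presences, stack, folds, candidates=[("lq", 1.0)], seed=0)
        assert all(0 <= a <= 1 for a in cv.metrics.auc_train + cv.metrics.auc_test)
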