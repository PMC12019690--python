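import numpy as np
import pytest
from scipy import stats

from kelpshift.grid import GridSpec
from kelpshift.stack import TEMPERATURE
from kelpshift.synthetic import (
    TruthResponse,
    make_world,
    sample_occurrences,
    truth_suitability,
)
from kelpshift.synthetic import truth_suitability_map


def test_future_temperature_is_present_plus_offset(small_world):
    present = small_world.present.layers[TEMPERATURE]
    future = small_world.futures["warm3"].layers[TEMPERATURE]
    valid = small_world.present.mask
    np.testing.assert_allclose(future[valid] - present[valid], 3.0)
    # other layers untouched
    np.testing.assert_array_equal(
        small_world.futures["warm3"].layers["salinity"][valid],
        small_world.present.layers["salinity"][valid],
    )


def test_same_seed_reproduces_world_bit_for_bit(small_grid):
    a = make_world(small_grid, {"warm3": 3.0}, seed=7, t_south=21.0)
    b = make_world(small_grid, {"warm3": 3.0}, seed=7, t_south=21.0)
    for name in a.present.variables:
        np.testing.assert_array_equal(a.present.layers[name], b.present.layers[name])
    np.testing.assert_array_equal(a.depth, b.depth)


def test_monotone_transform_layer_has_spearman_rho_one(small_world):
    rows, cols = small_world.present.valid_cells()
    t = small_world.present.layers[TEMPERATURE][rows, cols]
    dd = small_world.present.layers["degree_days"][rows, cols]
    rho = stats.spearmanr(t, dd).statistic
    assert rho == pytest.approx(1.0)


def test_degenerate_grid_errors_name_dimension():
    with pytest.raises(ValueError, match="n_rows"):
        make_world(GridSpec(0.0, 1.0, 0.0, 0.05, 0.05), {"w": 1.0}, seed=0)
    with pytest.raises(ValueError, match="n_cols"):
        make_world(GridSpec(0.0, 0.05, 0.0, 1.0, 0.05), {"w": 1.0}, seed=0)


class TestTruthSuitability:
    truth = TruthResponse(peak_temperature=15.0, thermal_sd=2.0, secondary_midpoint=30.0,
                          secondary_slope=1.0, max_occupancy_probability=0.8)

    def test_maximum_at_peak_with_saturated_secondary(self):
        s = truth_suitability({TEMPERATURE: 15.0, "salinity": 300.0}, self.truth)
        assert s == pytest.approx(0.8)

    def test_gaussian_tail_vanishes(self):
        s = truth_suitability({TEMPERATURE: 15.0 + 10 * 2.0, "salinity": 300.0}, self.truth)
        assert s < 1e-20 * 0.8

    def test_one_sd_from_peak_drops_by_exp_half(self):
        at_peak = truth_suitability({TEMPERATURE: 15.0, "salinity": 33.0}, self.truth)
        at_sd = truth_suitability({TEMPERATURE: 17.0, "salinity": 33.0}, self.truth)
        assert at_sd == pytest.approx(np.exp(-0.5) * at_peak)

    def test_missing_temperature_errors(self):
        with pytest.raises(KeyError):
            truth_suitability({"salinity": 33.0}, self.truth)


class TestSampleOccurrences:
    def test_zero_occupancy_is_unattainable(self, small_grid):
        truth = TruthResponse(max_occupancy_probability=1e-300)
        world = make_world(small_grid, {"w": 1.0}, seed=3, truth=truth, t_south=21.0)
        with pytest.raises(ValueError):
            sample_occurrences(world, 50, seed=0, max_passes=2)

    def test_mean_temperature_tracks_planted_peak(self, small_world):
        occ = sample_occurrences(small_world, 500, seed=9)
        grid = small_world.grid
        rows, cols = grid.cell_index(occ["longitude"].to_numpy(), occ["latitude"].to_numpy())
        t = small_world.present.layers[TEMPERATURE][rows, cols]
        assert abs(t.mean() - small_world.truth.peak_temperature) < 1.0
        # independent oracle: expectation of temperature under the planted
        # density, directly over the grid
        smap = truth_suitability_map(small_world)
        tall = small_world.present.layers[TEMPERATURE]
        valid = np.isfinite(smap)
        expected = (tall[valid] * smap[valid]).sum() / smap[valid].sum()
        assert abs(t.mean() - expected) < 0.5

    def test_records_stay_inside_their_cells_and_off_masked_cells(self, small_world):
        occ = sample_occurrences(small_world, 200, seed=2)
        grid = small_world.grid
        rows, cols = grid.cell_index(occ["longitude"].to_numpy(), occ["latitude"].to_numpy())
        assert small_world.present.mask[rows, cols].all()

    def test_reproducible_from_seed(self, small_world):
        a = sample_occurrences(small_world, 100, seed=4)
        b = sample_occurrences(small_world, 100, seed=4)
        assert a.equals(b)


def test_occurrence_density_proportional_to_suitability(small_world):
    """Chi-square goodness of fit of per-pass occupancy counts, binned on
    temperature, against the planted suitability (alpha = 0.01)."""
    smap = truth_suitability_map(small_world)
    valid = np.isfinite(smap)
    p = smap[valid]
    t = small_world.present.layers[TEMPERATURE][valid]
    n_passes = 2000
    rng = np.random.default_rng(17)
    counts_per_cell = rng.binomial(n_passes, p)
    edges = np.quantile(t, np.linspace(0, 1, 9))
    which = np.clip(np.digitize(t, edges[1:-1]), 0, 7)
    observed = np.bincount(which, weights=counts_per_cell, minlength=8)
    expected = np.bincount(which, weights=p * n_passes, minlength=8)
    keep = expected > 5
    # condition on the total: scale expected to the observed sum
    expected = expected[keep] * observed[keep].sum() / expected[keep].sum()
    stat, pval = stats.chisquare(observed[keep], expected)
    assert pval > 0.01
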