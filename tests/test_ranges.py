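import numpy as np
import pytest

from kelpshift.grid import GridSpec
from kelpshift.ranges import (
    BinaryMap,
    binarize,
    capture_threshold,
    cell_area_km2,
    loss_accounting,
    map_area_km2,
    recovery_accounting,
)

GRID = GridSpec(0.0, 0.25, 50.0, 50.15, 0.05)  # 3 x 5


def _bmap(suitable, threshold=0.5, grid=GRID, **kw):
    return BinaryMap(grid=grid, suitable=np.asarray(suitable, dtype=bool), threshold=threshold, **kw)


class TestCaptureThreshold:
    def test_twenty_point_ladder(self):
        s = np.arange(0.05, 1.0001, 0.05)  # 0.05 .. 1.00
        assert capture_threshold(s, capture=0.95) == pytest.approx(0.10)

    def test_full_capture_returns_minimum(self):
        s = np.arange(0.05, 1.0001, 0.05)
        assert capture_threshold(s, capture=1.0) == pytest.approx(0.05)

    def test_constant_suitabilities_return_that_value(self):
        assert capture_threshold(np.full(25, 0.4)) == pytest.approx(0.4)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            capture_threshold([])

    def test_capture_fraction_guaranteed(self, rng):
        s = rng.uniform(0, 1, 137)
        t = capture_threshold(s, capture=0.95)
        assert (s >= t).mean() >= 0.95


class TestBinarize:
    def test_threshold_above_max_gives_empty_map(self, rng):
        smap = rng.uniform(0, 0.8, GRID.shape)
        assert binarize(smap, 0.9, GRID).n_suitable == 0

    def test_tiny_threshold_keeps_all_valid_cells(self, rng):
        smap = rng.uniform(0.1, 0.8, GRID.shape)
        smap[0, 0] = np.nan  # masked
        out = binarize(smap, 1e-9, GRID)
        assert out.n_suitable == smap.size - 1
        assert not out.suitable[0, 0]


class TestCellArea:
    def test_equatorial_cell_at_default_resolution(self):
        assert cell_area_km2(0.0, 0.05) == pytest.approx(30.911, abs=1e-3)

    def test_sixty_degrees_is_half_equator(self):
        assert cell_area_km2(60.0, 0.05) == pytest.approx(cell_area_km2(0.0, 0.05) / 2)

    def test_region_area_is_sum_of_cells(self):
        cells = np.zeros(GRID.shape, dtype=bool)
        cells[0, 0] = cells[2, 4] = True
        expected = cell_area_km2(GRID.lat_centers[0], 0.05) + cell_area_km2(GRID.lat_centers[2], 0.05)
        assert map_area_km2(cells, GRID) == pytest.approx(expected)

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            cell_area_km2(90.0, 0.05)


class TestLossAccounting:
    def test_enumerated_three_cell_example(self):
        present = np.zeros(GRID.shape, dtype=bool)
        present[0, :3] = True  # cells A, B, C on one row
        future = np.zeros(GRID.shape, dtype=bool)
        future[0, 1] = True  # only B survives
        res = loss_accounting(_bmap(present), _bmap(future), basin_split_lon=-40.0)
        assert res.lost.sum() == 2
        assert res.contraction_pct == pytest.approx(66.667, abs=0.01)

    def test_expanding_future_has_no_loss(self):
        present = np.zeros(GRID.shape, dtype=bool)
        present[1, 1] = True
        future = present.copy()
        future[1, 2] = True
        res = loss_accounting(_bmap(present), _bmap(future))
        assert res.lost.sum() == 0 and res.contraction_pct == 0.0
        assert res.gained.sum() == 1

    def test_minimum_latitude_is_lowest_future_cell(self):
        present = np.ones(GRID.shape, dtype=bool)
        future = np.zeros(GRID.shape, dtype=bool)
        future[1, 0] = future[2, 0] = True
        res = loss_accounting(_bmap(present), _bmap(future))
        assert res.basin_min_suitable_lat["east"] == pytest.approx(GRID.lat_centers[1])
        assert np.isnan(res.basin_min_suitable_lat["west"])  # empty basin

    def test_empty_present_errors(self):
        empty = np.zeros(GRID.shape, dtype=bool)
        with pytest.raises(ValueError):
            loss_accounting(_bmap(empty), _bmap(empty))


class TestRecoveryAccounting:
    def test_enumerated_two_target_example(self):
        lost = np.zeros(GRID.shape, dtype=bool)
        lost[0, 0] = lost[0, 2] = True  # cells A and C
        k1 = np.zeros(GRID.shape, dtype=bool)
        k1[0, 0] = True  # k=1 recovers A
        k2 = k1.copy()
        k2[0, 2] = True  # k=2 recovers A and C
        ledger = recovery_accounting(lost, {1: _bmap(k1), 2: _bmap(k2)}, GRID)
        assert ledger.incremental_recovered_pct[1] == pytest.approx(50.0)
        assert ledger.incremental_recovered_pct[2] == pytest.approx(50.0)
        assert ledger.cumulative_recovered_pct[2] == pytest.approx(100.0)
        assert ledger.unrecovered_km2 == 0.0
        assert ledger.first_k_map[0, 0] == 1 and ledger.first_k_map[0, 2] == 2

    def test_nothing_recovered(self):
        lost = np.zeros(GRID.shape, dtype=bool)
        lost[0, :2] = True
        none = np.zeros(GRID.shape, dtype=bool)
        ledger = recovery_accounting(lost, {k: _bmap(none) for k in (1, 2, 3)}, GRID)
        assert ledger.unrecovered_km2 == pytest.approx(ledger.lost_area_km2)
        assert all(v == 0.0 for v in ledger.cumulative_recovered_pct.values())

    def test_identity_holds_on_random_maps(self, rng):
        lost = rng.random(GRID.shape) < 0.5
        maps = {k: _bmap(rng.random(GRID.shape) < 0.4) for k in (1, 2, 3, 4, 5)}
        ledger = recovery_accounting(lost, maps, GRID)
        assert ledger.identity_holds()
        inc_total = sum(ledger.incremental_recovered_km2.values())
        assert inc_total + ledger.unrecovered_km2 == pytest.approx(ledger.lost_area_km2)

    def test_non_monotone_cells_counted_not_double_booked(self):
        lost = np.zeros(GRID.shape, dtype=bool)
        lost[0, 0] = True
        yes = np.zeros(GRID.shape, dtype=bool)
        yes[0, 0] = True
        no = np.zeros(GRID.shape, dtype=bool)
        # recovered at k=1, flickers off at k=2, on again at k=3
        ledger = recovery_accounting(lost, {1: _bmap(yes), 2: _bmap(no), 3: _bmap(yes)}, GRID)
        assert ledger.n_nonmonotone_cells == 1
        assert ledger.first_k_map[0, 0] == 1
        assert ledger.identity_holds()
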