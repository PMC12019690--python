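"""Binarization, area accounting, and lost/recovered habitat bookkeeping.

Continuous cloglog suitability is binarized at a per-species threshold that
captures 95% of the occupied occurrence cells. Habitat lost under a future
scenario is the set of presently suitable cells no longer suitable under the
baseline future projection; habitat recovered at tolerance k is the part of
that lost set that the +k degC model projects as suitable again. Recovered
area is restricted to the lost set (newly colonized habitat is reported
separately and excluded from headline statistics), so the exact cell
identity ``lost = sum_k incremental(k) + unrecovered`` always holds. Areas
are in km^2 with the cell size shrinking as cos(latitude).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec

logger = logging.getLogger("kelpshift.ranges")

__all__ = [
    "BinaryMap",
    "LossResult",
    "RecoveryLedger",
    "capture_threshold",
    "binarize",
    "cell_area_km2",
    "map_area_km2",
    "loss_accounting",
    "recovery_accounting",
]

EARTH_RADIUS_KM = 6371.0088
UNRECOVERED_CODE = 255


@dataclass
class BinaryMap:
    """Suitable/unsuitable per valid cell at a stated threshold."""

    grid: GridSpec
    suitable: np.ndarray  # bool; False outside the valid mask
    threshold: float
    model_id: str = ""
    period: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        self.suitable = np.asarray(self.suitable, dtype=bool)
        if self.suitable.shape != self.grid.shape:
            raise ValueError("suitable map shape does not match grid")

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())

    def area_km2(self) -> float:
        return map_area_km2(self.suitable, self.grid)


def capture_threshold(occurrence_suitability, capture: float = 0.95) -> float:
    """Largest threshold keeping at least ``capture`` of occurrence cells suitable.

    Equals the ceil(capture * n)-th largest occurrence suitability. Warns
    below 20 occurrence cells (the order statistic is unstable there).
    """
    s = np.asarray(occurrence_suitability, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("no occurrence suitabilities supplied")
    if not (0 < capture <= 1):
        raise ValueError("capture must be in (0, 1]")
    if s.size < 20:
        logger.warning("capture_threshold: only %d occurrence cells; quantile is unstable", s.size)
    rank = int(np.ceil(capture * s.size))  # 1-based rank among descending values
    return float(np.sort(s)[::-1][rank - 1])


def binarize(suitability_map: np.ndarray, threshold: float, grid: GridSpec, model_id: str = "", period: str = "") -> BinaryMap:
    """Cell suitable iff cloglog >= threshold; masked (NaN) cells excluded."""
    arr = np.asarray(suitability_map, dtype=float)
    with np.errstate(invalid="ignore"):
        suitable = np.where(np.isfinite(arr), arr >= threshold, False)
    return BinaryMap(grid=grid, suitable=suitable, threshold=threshold, model_id=model_id, period=period)


def cell_area_km2(latitude_deg, resolution_deg: float):
    """Area of a resolution x resolution cell centered at the given latitude:
    ``(res * pi/180 * R)^2 * cos(lat)`` with R = 6371.0088 km."""
    lat = np.asarray(latitude_deg, dtype=float)
    if np.any(np.abs(lat) >= 90):
        raise ValueError("latitude must satisfy |lat| < 90")
    edge = resolution_deg * np.pi / 180.0 * EARTH_RADIUS_KM
    out = edge * edge * np.cos(np.deg2rad(lat))
    return float(out) if out.ndim == 0 else out


def map_area_km2(cells: np.ndarray, grid: GridSpec) -> float:
    """Total area of the True cells of a boolean map."""
    cells = np.asarray(cells, dtype=bool)
    per_row = cell_area_km2(grid.lat_centers, grid.resolution)
    return float((cells.sum(axis=1) * per_row).sum())


@dataclass
class LossResult:
    """Lost-cell set and the headline loss statistics for one scenario."""

    lost: np.ndarray  # bool cells: suitable now, unsuitable in the future baseline
    gained: np.ndarray  # bool cells: newly suitable (reported, not headline)
    present_area_km2: float
    future_area_km2: float
    lost_area_km2: float
    contraction_pct: float
    basin_contraction_pct: dict[str, float]
    basin_min_suitable_lat: dict[str, float]


def _basin_masks(grid: GridSpec, split_lon: float) -> dict[str, np.ndarray]:
    lon = grid.lon_grid()
    return {"west": lon < split_lon, "east": lon >= split_lon}


def loss_accounting(present: BinaryMap, future_base: BinaryMap, basin_split_lon: float = -40.0) -> LossResult:
    """Per-cell subtraction of binarized maps plus basin summaries.

    ``lost = suitable(present) & ~suitable(future)``; contraction is lost
    area over present suitable area (overall and per basin, split at the
    given meridian); the minimum suitable latitude is the lowest cell-center
    latitude among future-suitable cells per basin (NaN for an empty basin).
    """
    if present.grid != future_base.grid:
        raise ValueError("present and future maps are not congruent")
    grid = present.grid
    if present.n_suitable == 0:
        raise ValueError("present map has no suitable cells")
    lost = present.suitable & ~future_base.suitable
    gained = future_base.suitable & ~present.suitable
    lat = grid.lat_grid()
    basins = _basin_masks(grid, basin_split_lon)
    basin_contraction: dict[str, float] = {}
    basin_min_lat: dict[str, float] = {}
    for name, sel in basins.items():
        pres_b = map_area_km2(present.suitable & sel, grid)
        lost_b = map_area_km2(lost & sel, grid)
        basin_contraction[name] = 100.0 * lost_b / pres_b if pres_b > 0 else float("nan")
        fut = future_base.suitable & sel
        basin_min_lat[name] = float(lat[fut].min()) if fut.any() else float("nan")
    present_area = present.area_km2()
    lost_area = map_area_km2(lost, grid)
    return LossResult(
        lost=lost,
        gained=gained,
        present_area_km2=present_area,
        future_area_km2=future_base.area_km2(),
        lost_area_km2=lost_area,
        contraction_pct=100.0 * lost_area / present_area,
        basin_contraction_pct=basin_contraction,
        basin_min_suitable_lat=basin_min_lat,
    )


@dataclass
class RecoveryLedger:
    """Recovered-area accounting for one scenario across tolerance targets."""

    k_values: list[int]
    lost_area_km2: float
    cumulative_recovered_km2: dict[int, float]
    incremental_recovered_km2: dict[int, float]
    cumulative_recovered_pct: dict[int, float]
    incremental_recovered_pct: dict[int, float]
    unrecovered_km2: float
    unrecovered_pct: float
    first_k_map: np.ndarray  # 0 not lost, k first recovering target, 255 unrecovered
    n_nonmonotone_cells: int = 0
    extras: dict = field(default_factory=dict)

    def identity_holds(self) -> bool:
        """Exact cell identity: lost = sum incremental + unrecovered."""
        n_lost = int((self.first_k_map > 0).sum())
        n_inc = sum(int((self.first_k_map == k).sum()) for k in self.k_values)
        n_unrec = int((self.first_k_map == UNRECOVERED_CODE).sum())
        return n_lost == n_inc + n_unrec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "cumulative_recovered_km2": [self.cumulative_recovered_km2[k] for k in self.k_values],
                "incremental_recovered_km2": [self.incremental_recovered_km2[k] for k in self.k_values],
                "cumulative_recovered_pct": [self.cumulative_recovered_pct[k] for k in self.k_values],
                "incremental_recovered_pct": [self.incremental_recovered_pct[k] for k in self.k_values],
            }
        )


def recovery_accounting(lost: np.ndarray, future_maps: dict[int, BinaryMap], grid: GridSpec) -> RecoveryLedger:
    """Recovered-area bookkeeping over an ascending family of tolerance maps.

    ``cumulative(k) = lost & suitable(future, model k)``; ``incremental(k)``
    is the set of lost cells whose first recovering target is k; unrecovered
    cells are lost cells no target recovers. Cell-wise non-monotone
    cumulative sets (model noise) are permitted and logged. Percentages are
    relative to the lost area.
    """
    lost = np.asarray(lost, dtype=bool)
    k_values = sorted(int(k) for k in future_maps)
    if k_values != sorted(set(k_values)) or any(k < 1 for k in k_values):
        raise ValueError("tolerance targets must be distinct integers >= 1")
    lost_area = map_area_km2(lost, grid)

    first_k = np.zeros(grid.shape, dtype=np.int16)
    first_k[lost] = UNRECOVERED_CODE
    cumulative: dict[int, np.ndarray] = {}
    prev = np.zeros(grid.shape, dtype=bool)
    n_nonmono = 0
    for k in k_values:
        cum = lost & future_maps[k].suitable
        n_nonmono += int((prev & ~cum).sum())
        newly = cum & (first_k == UNRECOVERED_CODE)
        first_k[newly] = k
        cumulative[k] = cum
        prev = cum
    if n_nonmono:
        logger.info("recovery_accounting: %d cell-wise non-monotone recoveries (model noise)", n_nonmono)

    cum_km2 = {k: map_area_km2(cumulative[k], grid) for k in k_values}
    inc_km2 = {k: map_area_km2(first_k == k, grid) for k in k_values}
    unrecovered = lost & (first_k == UNRECOVERED_CODE)
    unrec_km2 = map_area_km2(unrecovered, grid)
    pct = lambda a: 100.0 * a / lost_area if lost_area > 0 else 0.0  # noqa: E731
    return RecoveryLedger(
        k_values=k_values,
        lost_area_km2=lost_area,
        cumulative_recovered_km2=cum_km2,
        incremental_recovered_km2=inc_km2,
        cumulative_recovered_pct={k: pct(v) for k, v in cum_km2.items()},
        incremental_recovered_pct={k: pct(v) for k, v in inc_km2.items()},
        unrecovered_km2=unrec_km2,
        unrecovered_pct=pct(unrec_km2),
        first_k_map=first_k,
        n_nonmonotone_cells=n_nonmono,
    )
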