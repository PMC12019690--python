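"""Regular lon/lat raster lattice shared by all layers and occurrence gridding.

Cells are half-open squares registered from the lower-left corner of the
study bounds: row 0 is the southernmost row, column 0 the westernmost
column, and a point sitting exactly on an interior cell boundary belongs to
the higher-index cell. Arrays indexed ``[row, col]`` therefore run
south-to-north; text-raster export flips to the conventional north-up order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max : float
        Study bounds in decimal degrees (WGS84).
    resolution : float
        Cell edge length in degrees. Defaults to 0.05 degrees, roughly
        5.5 km x 5.5 km at the equator.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 0.05

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("bounds must satisfy lon_min < lon_max and lat_min < lat_max")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must contain at least one cell per axis")

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of the center of cell ``(row, col)``."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon_min + (col + 0.5) * self.resolution
        lat = self.lat_min + (row + 0.5) * self.resolution
        return lon, lat

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to ``(row, col)``; half-open cells, lower-left origin.

        Points on an interior boundary fall in the higher-index cell (floor
        convention). Points outside the bounds map to indices outside
        ``[0, n_rows) x [0, n_cols)``; use :meth:`contains` to screen them.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # guard against float jitter putting exact centers on a boundary
        col = np.floor((lon - self.lon_min) / self.resolution + 1e-9).astype(int)
        row = np.floor((lat - self.lat_min) / self.resolution + 1e-9).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )

    def lat_grid(self) -> np.ndarray:
        """Latitude of every cell center, shape ``(n_rows, n_cols)``."""
        return np.broadcast_to(self.lat_centers[:, None], self.shape).copy()

    def lon_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lon_centers[None, :], self.shape).copy()

    @classmethod
    def north_atlantic(cls, resolution: float = 0.05) -> "GridSpec":
        """The full North Atlantic study window (-85..50 E, 35..75 N)."""
        return cls(-85.0, 50.0, 35.0, 75.0, resolution)
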