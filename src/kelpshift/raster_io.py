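"""Plain-text raster interchange (ESRI ASCII grid).

Layers live in memory as numpy arrays indexed ``[row, col]`` with row 0 at
the southern edge (see :mod:`kelpshift.grid`). On disk they follow the ESRI
ASCII grid convention: north-up rows, a six-line header, nodata tagged.
Coordinates are WGS84 lon/lat degrees.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import GridSpec

__all__ = ["write_ascii_grid", "read_ascii_grid"]

NODATA_DEFAULT = -9999.0


def write_ascii_grid(path, array: np.ndarray, grid: GridSpec, nodata: float = NODATA_DEFAULT) -> None:
    """Write ``array`` (south-up, NaN = masked) as an ESRI ASCII grid."""
    array = np.asarray(array, dtype=float)
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} does not match grid {grid.shape}")
    out = np.where(np.isfinite(array), array, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min:.10g}\n"
        f"yllcorner {grid.lat_min:.10g}\n"
        f"cellsize {grid.resolution:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns (south-up array with NaN nodata, GridSpec)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    res = header["cellsize"]
    grid = GridSpec(
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + ncols * res,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + nrows * res,
        resolution=res,
    )
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {data.shape} does not match header ({nrows}, {ncols})")
    data = data[::-1].copy()
    data[data == header["nodata_value"]] = np.nan
    return data, grid
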