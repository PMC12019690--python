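"""Occurrence record loading, curation, and gridding.

Records are curated the way presence-only distribution modelling expects:
malformed or out-of-range coordinates are rejected (and counted, never
silently lost), exact coordinate duplicates are collapsed, records with high
spatial uncertainty are removed, and the survivors are collapsed onto the
environmental grid so each occupied cell counts once regardless of sampling
effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec

logger = logging.getLogger("kelpshift.occurrences")

__all__ = ["OccurrenceSet", "GriddedOccurrences", "load_occurrences", "filter_occurrences", "grid_occurrences"]

#: duplicate = exact coordinate match after rounding to this many decimals
DEDUP_DECIMALS = 6
#: default spatial-uncertainty cutoff, metres (about two 0.05-deg cells)
DEFAULT_MAX_UNCERTAINTY_M = 10_000.0


@dataclass
class OccurrenceSet:
    """Curated presence records for one species."""

    species: str
    records: pd.DataFrame  # columns: longitude, latitude, uncertainty_m, source
    notes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GriddedOccurrences:
    """Occupied cells of a grid, with the raw-record collapse accounted for."""

    grid: GridSpec
    rows: np.ndarray
    cols: np.ndarray
    n_records: int  # raw records that fed the gridding
    n_masked_dropped: int = 0

    def __len__(self) -> int:
        return int(self.rows.size)

    def to_frame(self) -> pd.DataFrame:
        lon, lat = self.grid.cell_center(self.rows, self.cols)
        return pd.DataFrame({"row": self.rows, "col": self.cols, "lon": lon, "lat": lat})


def load_occurrences(path, species: str | None = None) -> OccurrenceSet:
    """Read an occurrence CSV (columns longitude, latitude, optional
    uncertainty_m / species / source).

    Rows with non-finite or out-of-range coordinates are rejected and logged;
    the note trail records how many. Missing coordinate columns raise with
    the columns actually found.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("longitude", "latitude") if c not in cols]
    if missing:
        raise ValueError(f"missing coordinate columns {missing}; found columns {list(df.columns)}")
    df = df.rename(columns={cols[k]: k for k in cols})
    if df.empty:
        raise ValueError(f"no records in {path}")
    if species is not None and "species" in df.columns:
        df = df[df["species"] == species]
        if df.empty:
            raise ValueError(f"no records for species {species!r} in {path}")
    name = species or (str(df["species"].iloc[0]) if "species" in df.columns else "unknown")

    notes: list[str] = []
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    ok = lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    n_bad = int((~ok).sum())
    if n_bad:
        msg = f"rejected {n_bad} malformed/out-of-range rows"
        notes.append(msg)
        logger.warning("load_occurrences: %s", msg)
    out = pd.DataFrame(
        {
            "longitude": lon[ok].astype(float),
            "latitude": lat[ok].astype(float),
            "uncertainty_m": pd.to_numeric(df.loc[ok, "uncertainty_m"], errors="coerce")
            if "uncertainty_m" in df.columns
            else np.nan,
            "source": df.loc[ok, "source"] if "source" in df.columns else str(path),
        }
    ).reset_index(drop=True)
    notes.append(f"loaded {len(out)} records from {path}")
    return OccurrenceSet(species=name, records=out, notes=notes)


def filter_occurrences(
    occ: OccurrenceSet,
    max_uncertainty_m: float = DEFAULT_MAX_UNCERTAINTY_M,
    bounds: GridSpec | None = None,
) -> OccurrenceSet:
    """Deduplicate and screen records.

    Exact duplicates (coordinates rounded to 6 decimals) collapse to one;
    records with uncertainty above ``max_uncertainty_m`` are removed (records
    with no uncertainty are kept and the count logged — the curated source
    datasets are treated as pre-screened); records outside ``bounds``
    (half-open, matching the grid convention) are removed. Order-independent.
    """
    if max_uncertainty_m <= 0:
        raise ValueError("max_uncertainty_m must be positive")
    df = occ.records.copy()
    notes = list(occ.notes)
    n0 = len(df)

    key = df[["longitude", "latitude"]].round(DEDUP_DECIMALS)
    df = df.loc[~key.duplicated()].copy()
    notes.append(f"collapsed {n0 - len(df)} duplicate records")

    unc = df["uncertainty_m"]
    n_unknown = int(unc.isna().sum())
    if n_unknown:
        notes.append(f"kept {n_unknown} records with unknown uncertainty")
        logger.info("filter_occurrences: kept %d records with unknown uncertainty", n_unknown)
    n1 = len(df)
    df = df[unc.isna() | (unc <= max_uncertainty_m)]
    notes.append(f"removed {n1 - len(df)} records with uncertainty > {max_uncertainty_m:g} m")

    if bounds is not None:
        n2 = len(df)
        df = df[bounds.contains(df["longitude"].to_numpy(), df["latitude"].to_numpy())]
        notes.append(f"removed {n2 - len(df)} records outside study bounds")

    df = df.sort_values(["longitude", "latitude"], kind="mergesort").reset_index(drop=True)
    if df.empty:
        logger.warning("filter_occurrences: no records survived filtering")
    return OccurrenceSet(species=occ.species, records=df, notes=notes)


def grid_occurrences(
    occ: OccurrenceSet,
    grid: GridSpec,
    mask: np.ndarray | None = None,
) -> GriddedOccurrences:
    """Collapse records onto grid cells (half-open cells, lower-left origin).

    Records outside the grid are dropped; when a validity ``mask`` is given,
    occupied cells falling on masked cells are dropped with the count
    reported. Each cell appears at most once.
    """
    lon = occ.records["longitude"].to_numpy()
    lat = occ.records["latitude"].to_numpy()
    inside = grid.contains(lon, lat)
    row, col = grid.cell_index(lon[inside], lat[inside])
    cells = np.unique(np.stack([row, col], axis=1), axis=0) if row.size else np.empty((0, 2), dtype=int)
    n_masked = 0
    if mask is not None and cells.size:
        keep = np.asarray(mask, dtype=bool)[cells[:, 0], cells[:, 1]]
        n_masked = int((~keep).sum())
        if n_masked:
            logger.info("grid_occurrences: dropped %d occupied cells outside the validity mask", n_masked)
        cells = cells[keep]
    return GriddedOccurrences(
        grid=grid,
        rows=cells[:, 0].astype(int),
        cols=cells[:, 1].astype(int),
        n_records=int(inside.sum()),
        n_masked_dropped=n_masked,
    )
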