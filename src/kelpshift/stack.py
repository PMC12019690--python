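"""Environmental raster stacks, validity masks, and correlation-based pruning.

An :class:`EnvStack` bundles named environmental layers (e.g. maximum sea
surface temperature in degC, salinity in PSS, phosphate in mol m-3) on one
:class:`~kelpshift.grid.GridSpec` with a single shared validity mask (sea
cells on the shelf). Variable pruning drops members of highly rank-correlated
pairs (Spearman |rho| above a threshold, default 0.8), never touching
protected variables such as temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec
from .raster_io import read_ascii_grid, write_ascii_grid

logger = logging.getLogger("kelpshift.stack")

__all__ = ["EnvStack", "load_stack", "apply_masks", "prune_correlated"]

#: canonical name of the temperature layer, protected throughout the pipeline
TEMPERATURE = "sst_max"


@dataclass
class EnvStack:
    """Named environmental layers on a shared grid and validity mask.

    ``layers[name]`` is a float array of shape ``grid.shape``; cells outside
    ``mask`` carry NaN. ``period`` labels the climatology ("present" or a
    scenario name).
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray
    period: str = "present"
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} does not match grid {self.grid.shape}")
            arr = arr.copy()
            arr[~self.mask] = np.nan
            self.layers[name] = arr

    @property
    def variables(self) -> list[str]:
        return sorted(self.layers)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of valid cells, row-major order."""
        return np.nonzero(self.mask)

    def table(self, rows=None, cols=None, variables: Iterable[str] | None = None) -> pd.DataFrame:
        """Variable values at the given cells (defaults to all valid cells)."""
        if rows is None:
            rows, cols = self.valid_cells()
        variables = sorted(variables) if variables is not None else self.variables
        return pd.DataFrame({name: self.layers[name][rows, cols] for name in variables})

    def select(self, variables: Iterable[str]) -> "EnvStack":
        variables = list(variables)
        missing = [v for v in variables if v not in self.layers]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return EnvStack(
            grid=self.grid,
            layers={v: self.layers[v] for v in variables},
            mask=self.mask.copy(),
            period=self.period,
            units={v: self.units.get(v, "") for v in variables},
        )

    def with_layer(self, name: str, array: np.ndarray) -> "EnvStack":
        """Copy of the stack with one layer replaced or added."""
        layers = {k: v.copy() for k, v in self.layers.items()}
        layers[name] = np.asarray(array, dtype=float)
        return EnvStack(self.grid, layers, self.mask.copy(), self.period, dict(self.units))

    def write(self, directory, prefix: str = "") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in self.variables:
            path = directory / f"{prefix}{name}_{self.period}.asc"
            write_ascii_grid(path, self.layers[name], self.grid)
            paths.append(path)
        return paths


def load_stack(paths: Mapping[str, str | Path], period: str = "present") -> EnvStack:
    """Load named ASCII-grid layers into one stack with a union nodata mask.

    All files must share the exact grid geometry; offenders are listed in the
    raised error. A cell that is nodata in any layer is masked in all layers.
    """
    layers: dict[str, np.ndarray] = {}
    grids: dict[str, GridSpec] = {}
    for name, path in paths.items():
        layers[name], grids[name] = read_ascii_grid(path)
    ref_name = next(iter(grids))
    ref = grids[ref_name]
    offenders = [name for name, g in grids.items() if g != ref]
    if offenders:
        raise ValueError(
            f"layer geometry mismatch: {offenders} do not match {ref_name!r} "
            f"({ref.shape} @ {ref.resolution} deg)"
        )
    mask = np.ones(ref.shape, dtype=bool)
    for arr in layers.values():
        mask &= np.isfinite(arr)
    return EnvStack(grid=ref, layers=layers, mask=mask, period=period)


def apply_masks(
    stack: EnvStack,
    depth: np.ndarray,
    max_depth_m: float = 200.0,
    bounds: GridSpec | None = None,
) -> EnvStack:
    """Restrict a stack to the shelf: depth <= ``max_depth_m`` (inclusive),
    optionally clipped to ``bounds``. Returns a new stack; the retained-cell
    count is logged.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.shape != stack.grid.shape:
        raise ValueError("depth raster not congruent with stack grid")
    keep = stack.mask & np.isfinite(depth) & (depth <= max_depth_m)
    if bounds is not None:
        lon = stack.grid.lon_grid()
        lat = stack.grid.lat_grid()
        keep &= bounds.contains(lon, lat)
    n = int(keep.sum())
    if n == 0:
        logger.warning("apply_masks: no cells retained (all deeper than %.0f m or out of bounds)", max_depth_m)
    logger.info("apply_masks: retained %d of %d valid cells", n, stack.n_valid)
    return EnvStack(
        grid=stack.grid,
        layers={k: v.copy() for k, v in stack.layers.items()},
        mask=keep,
        period=stack.period,
        units=dict(stack.units),
    )


def correlation_table(sample: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of the sampled cells."""
    rho = stats.spearmanr(sample.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1) and sample.shape[1] == 2:  # spearmanr collapses 2-var case
        r = stats.spearmanr(sample.iloc[:, 0], sample.iloc[:, 1]).statistic
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=sample.columns, columns=sample.columns)


def prune_correlated(
    stack: EnvStack,
    threshold: float = 0.8,
    protected: Iterable[str] = (TEMPERATURE,),
    max_sample: int = 10_000,
    seed: int = 0,
    full_grid: bool = False,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Greedy elimination of rank-correlated variables.

    Spearman |rho| is computed on a seeded subsample of at most ``max_sample``
    valid cells (or all of them with ``full_grid``). While any pair that is
    not wholly protected exceeds ``threshold``, the unprotected variable with
    the largest mean |rho| against all remaining variables is dropped, ties
    broken by dropping the alphabetically later name. Protected variables are
    never dropped.

    Returns ``(kept, dropped, correlation_table)`` with the table computed on
    the original variable set.
    """
    protected = set(protected)
    missing = protected - set(stack.layers)
    if missing:
        raise KeyError(f"protected variables absent from stack: {sorted(missing)}")
    if len(stack.layers) < 2:
        raise ValueError("need at least two variables to prune")
    rows, cols = stack.valid_cells()
    if not full_grid and rows.size > max_sample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(rows.size, size=max_sample, replace=False)
        rows, cols = rows[idx], cols[idx]
    if rows.size < 10:
        raise ValueError("need at least 10 valid cells to estimate correlations")
    sample = stack.table(rows, cols)
    corr = correlation_table(sample)

    kept = list(corr.columns)
    dropped: list[str] = []
    while True:
        sub = corr.loc[kept, kept].abs()
        violating: set[str] = set()
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if sub.loc[a, b] > threshold and not ({a, b} <= protected):
                    violating.update({a, b} - protected)
        if not violating:
            break
        # mean |rho| against all other remaining variables
        mean_rho = {v: (sub.loc[v, kept].sum() - 1.0) / max(len(kept) - 1, 1) for v in violating}
        victim = max(sorted(violating), key=lambda v: (mean_rho[v], v))
        kept.remove(victim)
        dropped.append(victim)
        logger.info("prune_correlated: dropped %r (mean |rho| %.3f)", victim, mean_rho[victim])
    return sorted(kept), sorted(dropped), corr
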