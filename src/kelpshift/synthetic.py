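"""Seeded synthetic study worlds with a planted thermal niche.

The generator emulates the structure of a marine environmental stack for a
cold-adapted, shelf-dwelling species: a maximum sea-surface-temperature layer
with a south-to-north cooling gradient, a salinity layer (the secondary niche
axis), a phosphate layer, a layer that is a strictly increasing transform of
temperature (so rank-correlation pruning has something to remove), a
pure-noise layer (so the low-contribution filter has something to remove),
and a land mask with a coastal shelf shallower than 200 m. Future scenarios
warm the temperature layer by a stated offset, leaving other layers
unchanged. Everything is a pure function of (parameters, seed).

The planted occupancy truth is unimodal in temperature (Gaussian kernel
around a thermal optimum) times a saturating logistic response in the
secondary variable; occurrences are Bernoulli draws from it. Ground truth is
known exactly, which is what makes the downstream model pipeline testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import GridSpec
from .stack import TEMPERATURE, EnvStack

logger = logging.getLogger("kelpshift.synthetic")

__all__ = ["TruthResponse", "WorldBundle", "make_world", "truth_suitability", "sample_occurrences", "default_grid"]


def default_grid() -> GridSpec:
    """Desk-scale default window: 200 x 300 cells at 0.05 deg."""
    return GridSpec(lon_min=-10.0, lon_max=5.0, lat_min=50.0, lat_max=60.0, resolution=0.05)


@dataclass(frozen=True)
class TruthResponse:
    """Planted occupancy probability: Gaussian in temperature x logistic in a
    secondary variable, scaled to ``max_occupancy_probability``."""

    peak_temperature: float = 17.0  # degC; cold-temperate optimum
    thermal_sd: float = 1.0  # degC
    secondary_variable: str = "salinity"
    secondary_midpoint: float = 33.0  # PSS
    secondary_slope: float = 1.5  # per PSS
    max_occupancy_probability: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.max_occupancy_probability <= 1):
            raise ValueError("max_occupancy_probability must be in (0, 1]")
        if self.thermal_sd <= 0:
            raise ValueError("thermal_sd must be positive")


@dataclass
class WorldBundle:
    """A present stack, its future scenarios, the bathymetry, and the truth."""

    present: EnvStack
    futures: dict[str, EnvStack]
    depth: np.ndarray  # metres below sea level; NaN over land
    land_mask: np.ndarray  # True on land
    truth: TruthResponse
    seed: int
    scenario_offsets: dict[str, float] = field(default_factory=dict)

    @property
    def grid(self) -> GridSpec:
        return self.present.grid


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated noise (blurred white noise)."""
    white = rng.standard_normal(shape)
    if sigma_cells <= 0:
        return white
    smooth = gaussian_filter(white, sigma=sigma_cells, mode="nearest")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_world(
    grid: GridSpec | None = None,
    scenario_offsets: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    truth: TruthResponse | None = None,
    t_south: float = 27.0,
    lat_gradient: float = 2.0,
    noise_sd_temperature: float = 0.8,
    noise_length_scale_deg: float = 0.5,
    land_fraction: float = 0.2,
    depth_scale_m: float = 150.0,
    latitude_warming_gradient: float = 0.0,
) -> WorldBundle:
    """Generate a seeded synthetic world.

    Parameters
    ----------
    grid
        Study lattice; defaults to the 200 x 300 desk-scale window.
    scenario_offsets
        Mapping scenario name -> warming offset in degC added to the present
        temperature layer (at least one must be >= 0). With
        ``latitude_warming_gradient`` g non-zero the offset varies linearly
        with latitude as ``offset + g * (lat - lat_mid)``.
    seed
        Seeds every random field; identical calls are bit-identical.
    t_south, lat_gradient
        Deterministic temperature backbone: ``t_south - lat_gradient * (lat -
        lat_min)`` degC, a monotone south-to-north cooling.
    noise_sd_temperature, noise_length_scale_deg
        Amplitude (degC) and Gaussian length scale (degrees) of the smooth
        noise added to every field.
    land_fraction, depth_scale_m
        Fraction of cells turned into land (eastern-biased elevation field)
        and the metres-per-unit-elevation factor that shapes the shelf.
    """
    if grid is None:
        grid = default_grid()
    if grid.n_rows < 2:
        raise ValueError("degenerate grid: n_rows must be >= 2")
    if grid.n_cols < 2:
        raise ValueError("degenerate grid: n_cols must be >= 2")
    scenario_offsets = dict(scenario_offsets or {})
    if scenario_offsets and not any(v >= 0 for v in scenario_offsets.values()):
        raise ValueError("at least one scenario offset must be >= 0")
    truth = truth or TruthResponse()

    rng = np.random.default_rng(seed)
    shape = grid.shape
    sigma = noise_length_scale_deg / grid.resolution
    lat = grid.lat_grid()
    lon = grid.lon_grid()

    temperature = t_south - lat_gradient * (lat - grid.lat_min)
    temperature = temperature + noise_sd_temperature * _smooth_field(rng, shape, sigma)
    salinity = 33.0 + 2.0 * _smooth_field(rng, shape, sigma)
    phosphate = np.clip(0.4 + 0.25 * _smooth_field(rng, shape, sigma), 0.01, None)
    # strictly increasing transform of temperature -> Spearman rho = 1 with it
    degree_days = 12.0 * np.exp(temperature / 10.0)
    turbidity = np.clip(5.0 + 2.0 * _smooth_field(rng, shape, sigma), 0.05, None)

    # elevation: smooth field plus an eastward continental trend; land above a
    # quantile chosen so roughly land_fraction of cells are dry
    lon_span = grid.lon_max - grid.lon_min
    elevation = _smooth_field(rng, shape, 2.0 * sigma) + 1.5 * (lon - grid.lon_min) / lon_span
    coast_level = float(np.quantile(elevation, 1.0 - land_fraction))
    land_mask = elevation > coast_level
    depth = (coast_level - elevation) * depth_scale_m
    depth[land_mask] = np.nan

    sea_mask = ~land_mask
    units = {
        TEMPERATURE: "degC",
        "salinity": "PSS",
        "phosphate": "mol m-3",
        "degree_days": "degC d",
        "turbidity": "NTU",
    }
    layers = {
        TEMPERATURE: temperature,
        "salinity": salinity,
        "phosphate": phosphate,
        "degree_days": degree_days,
        "turbidity": turbidity,
    }
    present = EnvStack(grid=grid, layers=layers, mask=sea_mask, period="present", units=units)

    futures: dict[str, EnvStack] = {}
    lat_mid = 0.5 * (grid.lat_min + grid.lat_max)
    for name, offset in scenario_offsets.items():
        offset_field = offset + latitude_warming_gradient * (lat - lat_mid)
        future_layers = {k: v.copy() for k, v in present.layers.items()}
        future_layers[TEMPERATURE] = future_layers[TEMPERATURE] + offset_field
        futures[name] = EnvStack(grid=grid, layers=future_layers, mask=sea_mask.copy(), period=name, units=units)

    return WorldBundle(
        present=present,
        futures=futures,
        depth=depth,
        land_mask=land_mask,
        truth=truth,
        seed=seed,
        scenario_offsets=scenario_offsets,
    )


def truth_suitability(env_values: Mapping[str, np.ndarray | float], truth: TruthResponse):
    """Planted occupancy probability at given environmental values.

    Gaussian kernel in temperature centered at ``peak_temperature`` times a
    logistic response in the secondary variable (treated as saturated when the
    secondary variable is absent), scaled by ``max_occupancy_probability``.
    """
    if TEMPERATURE not in env_values:
        raise KeyError(f"temperature value ({TEMPERATURE!r}) required")
    t = np.asarray(env_values[TEMPERATURE], dtype=float)
    z = (t - truth.peak_temperature) / truth.thermal_sd
    kernel = np.exp(-0.5 * z * z)
    if truth.secondary_variable in env_values:
        v = np.asarray(env_values[truth.secondary_variable], dtype=float)
        kernel = kernel * expit(truth.secondary_slope * (v - truth.secondary_midpoint))
    out = truth.max_occupancy_probability * kernel
    return float(out) if out.ndim == 0 else out


def truth_suitability_map(world: WorldBundle, stack: EnvStack | None = None) -> np.ndarray:
    """Suitability of every cell (NaN outside the stack mask)."""
    stack = stack or world.present
    out = np.full(stack.grid.shape, np.nan)
    rows, cols = stack.valid_cells()
    values = {name: stack.layers[name][rows, cols] for name in stack.variables}
    out[rows, cols] = truth_suitability(values, world.truth)
    return out


def sample_occurrences(
    world: WorldBundle,
    n_target: int,
    seed: int = 0,
    species: str = "synthetic_kelp",
    max_passes: int = 50,
    uncertainty_m: float = 500.0,
) -> pd.DataFrame:
    """Draw occurrence records from the planted occupancy truth.

    Each pass draws every valid cell Bernoulli(truth suitability); passes
    accumulate occupied cells until at least ``n_target`` are occupied (or the
    pass cap is hit, which raises with the attainable count). One record is
    emitted per occupied cell at the cell center plus seeded sub-cell jitter;
    if more than ``n_target`` cells are occupied a seeded uniform subsample of
    exactly ``n_target`` is kept, which preserves the suitability-proportional
    density.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    stack = world.present
    rows, cols = stack.valid_cells()
    values = {name: stack.layers[name][rows, cols] for name in stack.variables}
    p = np.asarray(truth_suitability(values, world.truth), dtype=float)
    if p.max() <= 0:
        raise ValueError("no cells attainable: planted suitability is zero everywhere")

    occupied = np.zeros(p.size, dtype=bool)
    for _ in range(max_passes):
        occupied |= rng.random(p.size) < p
        if occupied.sum() >= n_target:
            break
    else:
        raise ValueError(
            f"could not reach n_target={n_target} occupied cells within "
            f"{max_passes} passes; attainable: {int(occupied.sum())}"
        )

    idx = np.nonzero(occupied)[0]
    if idx.size > n_target:
        idx = rng.choice(idx, size=n_target, replace=False)
        idx.sort()
    r, c = rows[idx], cols[idx]
    lon, lat = stack.grid.cell_center(r, c)
    half = stack.grid.resolution / 2.0
    jitter = lambda n: rng.uniform(-0.999 * half, 0.999 * half, size=n)  # noqa: E731
    records = pd.DataFrame(
        {
            "species": species,
            "longitude": lon + jitter(idx.size),
            "latitude": lat + jitter(idx.size),
            "uncertainty_m": uncertainty_m,
        }
    )
    logger.info("sample_occurrences: %d records from %d occupied cells", len(records), int(occupied.sum()))
    return records
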