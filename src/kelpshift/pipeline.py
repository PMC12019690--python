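"""End-to-end orchestration: synthetic world -> curated occurrences ->
variable selection -> blocked cross-validation -> binarization ->
tolerance-family training -> loss/recovery ledger.

A :class:`RunConfig` fully determines a run; :func:`run` executes the stages
in order, logs cell counts at every filter, writes all artifacts (text
rasters, CSV/JSON tables, a manifest with config, seeds, and software
versions) to the output directory, and returns the in-memory results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blockcv import (
    CVResult,
    choose_block_size,
    cross_validate,
    ensemble_map,
    ensemble_response_curve,
    make_folds_with_presences,
    tss,
)
from .grid import GridSpec
from .maxnet import MaxNet
from .occurrences import GriddedOccurrences, filter_occurrences, grid_occurrences, load_occurrences
from .ranges import BinaryMap, LossResult, RecoveryLedger, binarize, capture_threshold, loss_accounting, recovery_accounting
from .raster_io import write_ascii_grid
from .stack import TEMPERATURE, EnvStack, apply_masks, prune_correlated
from .synthetic import TruthResponse, make_world, sample_occurrences
from .tolerance import ShiftedEnsemble, shifted_capture_threshold, train_shifted_family

logger = logging.getLogger("kelpshift.pipeline")

__all__ = ["RunConfig", "RunResult", "contribution_filter", "run", "report"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run (synthetic-world mode).

    Defaults are the desk-scale study conditions: a 200 x 300 cell window at
    0.05 deg, a planted thermal optimum of 17 degC, about 500 occurrence
    records, 5 spatial folds, the linear/quadratic/product candidate ladder
    at beta multiplier 1, a 95% occurrence-capture threshold, tolerance
    targets +1..+5 degC, and two uniform-warming scenarios.
    """

    species: str = "synthetic_kelp"
    seed: int = 0
    # world
    grid_bounds: tuple[float, float, float, float] = (-10.0, 5.0, 50.0, 60.0)  # lon_min, lon_max, lat_min, lat_max
    resolution: float = 0.05
    scenario_offsets: dict[str, float] = field(default_factory=lambda: {"ssp_low": 1.5, "ssp_high": 3.0})
    truth_peak_temperature: float = 17.0
    truth_thermal_sd: float = 1.0
    n_occurrences: int = 500
    # curation
    max_depth_m: float = 200.0
    max_uncertainty_m: float = 10_000.0
    # variable selection
    correlation_threshold: float = 0.8
    contribution_threshold_pct: float = 5.0
    # cross-validation
    candidates: tuple[tuple[str, float], ...] = (("l", 1.0), ("lq", 1.0), ("lqp", 1.0))
    folds_k: int = 5
    block_size_candidates: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)
    background_cap: int = 50_000
    # binarization and tolerance family
    capture: float = 0.95
    tolerance_k: tuple[int, ...] = (1, 2, 3, 4, 5)
    increase_rate: float = 2.0
    calibration: str = "full"
    # accounting
    basin_split_lon: float = -40.0
    # output
    write_rasters: bool = True

    def grid(self) -> GridSpec:
        lon_min, lon_max, lat_min, lat_max = self.grid_bounds
        return GridSpec(lon_min, lon_max, lat_min, lat_max, self.resolution)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidates"] = [list(c) for c in self.candidates]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "candidates" in d:
            d["candidates"] = tuple((str(c), float(m)) for c, m in d["candidates"])
        for key in ("grid_bounds", "block_size_candidates", "tolerance_k"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    """In-memory outcome of a pipeline run (everything also lands on disk)."""

    config: RunConfig
    outdir: Path
    stack: EnvStack  # pruned/selected present stack on the shelf mask
    presences: GriddedOccurrences
    kept_variables: list[str]
    dropped_correlated: list[str]
    dropped_contribution: list[str]
    importance: pd.Series
    block_size_deg: float
    cv: CVResult
    suitability_peak: float
    threshold: float
    present_binary: BinaryMap
    scenario_losses: dict[str, LossResult]
    family: dict[int, ShiftedEnsemble]
    ledgers: dict[str, RecoveryLedger]
    metrics: dict


def contribution_filter(
    stack: EnvStack,
    presences: GriddedOccurrences,
    threshold_pct: float = 5.0,
    protected: tuple[str, ...] = (TEMPERATURE,),
    candidate: tuple[str, float] = ("lqp", 1.0),
    background_cap: int = 50_000,
    n_repeats: int = 5,
    seed: int = 0,
    max_rounds: int = 2,
) -> tuple[list[str], list[pd.Series]]:
    """Iteratively drop variables contributing below ``threshold_pct``.

    A model is fitted at the given hyperparameters on all presences against
    the (capped) background; permutation importance is computed; variables
    below the threshold are dropped (temperature always kept, logged if it
    would fall); the model is refitted with the survivors. At most
    ``max_rounds`` rounds. Returns (retained variables, per-round importance
    series); the first round covers every variable entering the filter.
    """
    if len(stack.variables) < 2:
        raise ValueError("need at least two variables after correlation pruning")
    rng = np.random.default_rng(seed)
    rows, cols = stack.valid_cells()
    if rows.size > background_cap:
        idx = rng.choice(rows.size, background_cap, replace=False)
        rows, cols = rows[idx], cols[idx]
    keep = list(stack.variables)
    rounds: list[pd.Series] = []
    for round_no in range(max_rounds):
        X = pd.concat(
            [stack.table(presences.rows, presences.cols, keep), stack.table(rows, cols, keep)],
            ignore_index=True,
        )
        y = np.concatenate([np.ones(len(presences)), np.zeros(rows.size)])
        est = MaxNet(feature_classes=candidate[0], beta_multiplier=candidate[1])
        with np.errstate(over="ignore"):
            est.fit(X, y)
        importance = est.permutation_importance(X, y, n_repeats=n_repeats, seed=seed + round_no)
        rounds.append(importance)
        low = [v for v in keep if importance[v] < threshold_pct and v not in protected]
        for v in keep:
            if importance[v] < threshold_pct and v in protected:
                logger.info("contribution_filter: %r below %s%% but protected, kept", v, threshold_pct)
        if not low:
            break
        logger.info("contribution_filter: round %d dropped %s", round_no + 1, low)
        keep = [v for v in keep if v not in low]
        if len(keep) == 1:
            logger.warning("contribution_filter: only %r survives; keeping it alone", keep[0])
            break
    return keep, rounds


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, outdir) -> RunResult:
    """Execute the full pipeline; see the module docstring for the stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if not config.scenario_offsets:
            raise ValueError("config lists no scenarios (scenario_offsets is empty)")
        # ---------------------------------------------------------- world
        stage = "synthetic world"
        grid = config.grid()
        truth = TruthResponse(
            peak_temperature=config.truth_peak_temperature, thermal_sd=config.truth_thermal_sd
        )
        world = make_world(grid, config.scenario_offsets, seed=config.seed, truth=truth)
        logger.info("[%s] grid %dx%d, %d sea cells", stage, grid.n_rows, grid.n_cols, world.present.n_valid)

        stage = "masks"
        present = apply_masks(world.present, world.depth, max_depth_m=config.max_depth_m)
        futures = {
            name: apply_masks(stk, world.depth, max_depth_m=config.max_depth_m)
            for name, stk in world.futures.items()
        }
        logger.info("[%s] %d shelf cells (depth <= %.0f m)", stage, present.n_valid, config.max_depth_m)

        # ----------------------------------------------------- occurrences
        stage = "occurrences"
        occ_path = outdir / "occurrences.csv"
        records = sample_occurrences(world, config.n_occurrences, seed=config.seed + 1, species=config.species)
        records.to_csv(occ_path, index=False)
        occ = load_occurrences(occ_path, species=config.species)
        occ = filter_occurrences(occ, max_uncertainty_m=config.max_uncertainty_m, bounds=grid)
        presences = grid_occurrences(occ, grid, mask=present.mask)
        logger.info("[%s] %d records -> %d occupied cells", stage, len(occ), len(presences))
        if len(presences) < 20:
            raise RuntimeError(f"only {len(presences)} occupied cells; world too sparse")

        # ------------------------------------------------ variable pruning
        stage = "correlation pruning"
        kept, dropped_corr, corr = prune_correlated(
            present, threshold=config.correlation_threshold, seed=config.seed
        )
        corr.to_csv(outdir / "correlations.csv")
        present_kept = present.select(kept)
        logger.info("[%s] kept %s, dropped %s", stage, kept, dropped_corr)

        stage = "contribution filter"
        kept2, importance_rounds = contribution_filter(
            present_kept,
            presences,
            threshold_pct=config.contribution_threshold_pct,
            background_cap=config.background_cap,
            seed=config.seed,
        )
        dropped_contrib = sorted(set(kept) - set(kept2))
        importance = importance_rounds[0]  # full-variable contributions
        pd.DataFrame({f"round_{i + 1}": r for i, r in enumerate(importance_rounds)}).to_csv(
            outdir / "importance.csv"
        )
        stack = present_kept.select(kept2)
        futures = {name: stk.select(kept2) for name, stk in futures.items()}
        logger.info("[%s] kept %s, dropped %s", stage, kept2, dropped_contrib)

        # --------------------------------------------------------- blockCV
        stage = "block cross-validation"
        block_size = choose_block_size(
            stack.layers[TEMPERATURE], grid, config.block_size_candidates, seed=config.seed, mask=stack.mask
        )
        folds = make_folds_with_presences(grid, stack.mask, presences, block_size, k=config.folds_k, seed=config.seed)
        cv = cross_validate(
            presences, stack, folds, candidates=config.candidates,
            background_cap=config.background_cap, seed=config.seed,
        )
        cv.candidate_table.to_csv(outdir / "candidates.csv", index=False)

        # --------------------------------------- response curve, threshold
        stage = "binarization"
        curve_temps, curve_values = ensemble_response_curve(cv.fits, TEMPERATURE)
        peak = float(curve_temps[int(np.argmax(curve_values))])
        occ_suit = cv.mean_map[presences.rows, presences.cols]
        threshold = capture_threshold(occ_suit, capture=config.capture)
        present_bin = binarize(cv.mean_map, threshold, grid, model_id="base", period="present")
        logger.info(
            "[%s] peak %.2f degC, threshold %.4f, %d suitable cells",
            stage, peak, threshold, present_bin.n_suitable,
        )

        stage = "baseline projection"
        scenario_losses: dict[str, LossResult] = {}
        base_future_bins: dict[str, BinaryMap] = {}
        for name, fut in futures.items():
            fmap = ensemble_map(cv.fits, fut)
            fbin = binarize(fmap, threshold, grid, model_id="base", period=name)
            base_future_bins[name] = fbin
            scenario_losses[name] = loss_accounting(present_bin, fbin, config.basin_split_lon)
            logger.info(
                "[%s] %s: %.0f km2 lost (%.1f%% contraction)",
                stage, name, scenario_losses[name].lost_area_km2, scenario_losses[name].contraction_pct,
            )

        # ------------------------------------------------ tolerance family
        stage = "tolerance family"
        family = train_shifted_family(
            presences,
            stack,
            folds,
            cv.chosen,
            (curve_temps, curve_values),
            threshold,
            peak,
            k_list=config.tolerance_k,
            increase_rate=config.increase_rate,
            calibration=config.calibration,
            background_rows=cv.background_rows,
            background_cols=cv.background_cols,
            capture=config.capture,
        )
        if set(family) != set(config.tolerance_k):
            raise RuntimeError(f"tolerance family incomplete: trained {sorted(family)} of {config.tolerance_k}")

        stage = "recovery accounting"
        # per-k binarization threshold: same 95%-capture rule as the base
        # model, with occurrences scored in each model's training environment
        # (its warped present layer); scenario independent
        k_thresholds: dict[int, float] = {
            k: shifted_capture_threshold(ens, stack, presences, capture=config.capture)
            for k, ens in family.items()
        }
        ledgers: dict[str, RecoveryLedger] = {}
        for name, fut in futures.items():
            future_maps: dict[int, BinaryMap] = {}
            for k, ens in family.items():
                kmap = ensemble_map(ens.fits, fut)
                future_maps[k] = binarize(kmap, k_thresholds[k], grid, model_id=f"k{k}", period=name)
            ledgers[name] = recovery_accounting(scenario_losses[name].lost, future_maps, grid)
            assert ledgers[name].identity_holds()

        # ---------------------------------------------------------- output
        stage = "outputs"
        tss_values = []
        for f, est in enumerate(cv.fits, start=1):
            test = np.concatenate(
                [
                    folds.fold_of_cells(presences.rows, presences.cols) == f,
                    folds.fold_of_cells(cv.background_rows, cv.background_cols) == f,
                ]
            )
            X = pd.concat(
                [
                    stack.table(presences.rows, presences.cols),
                    stack.table(cv.background_rows, cv.background_cols),
                ],
                ignore_index=True,
            )
            y = np.concatenate([np.ones(len(presences)), np.zeros(cv.background_rows.size)])
            pred = est.predict(X[test], output="cloglog") >= threshold
            tss_values.append(tss(pred, y[test]))
        cv.metrics.tss_test = tss_values
        cv.metrics.tss_threshold = threshold

        metrics = {
            "species": config.species,
            "n_occurrence_cells": len(presences),
            "kept_variables": kept2,
            "contribution_pct": {v: float(importance[v]) for v in importance.index},
            "chosen_candidate": list(cv.chosen),
            "block_size_deg": block_size,
            "mean_auc_train": cv.metrics.mean_auc_train,
            "mean_auc_test": cv.metrics.mean_auc_test,
            "mean_tss_test": cv.metrics.mean_tss_test,
            "suitability_peak_degC": peak,
            "threshold": threshold,
            "present_suitable_km2": present_bin.area_km2(),
            "temperature_increase_by_k": {k: family[k].transform.temperature_increase for k in sorted(family)},
            "scenarios": {
                name: {
                    "lost_km2": scenario_losses[name].lost_area_km2,
                    "contraction_pct": scenario_losses[name].contraction_pct,
                    "min_suitable_lat": scenario_losses[name].basin_min_suitable_lat,
                    "cumulative_recovered_pct": ledgers[name].cumulative_recovered_pct,
                    "unrecovered_pct": ledgers[name].unrecovered_pct,
                }
                for name in futures
            },
        }
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1, default=float)
        cv.metrics.to_frame().to_csv(outdir / "fold_metrics.csv", index=False)
        report(ledgers, scenario_losses).to_csv(outdir / "ledger.csv", index=False)
        with open(outdir / "ledger.json", "w") as fh:
            json.dump(metrics["scenarios"], fh, indent=1, default=float)
        if config.write_rasters:
            raster_dir = outdir / "rasters"
            raster_dir.mkdir(exist_ok=True)
            write_ascii_grid(raster_dir / "suitability_present.asc", cv.mean_map, grid)
            write_ascii_grid(raster_dir / "binary_present.asc", present_bin.suitable.astype(float), grid)
            for name in futures:
                write_ascii_grid(
                    raster_dir / f"binary_{name}_base.asc", base_future_bins[name].suitable.astype(float), grid
                )
                write_ascii_grid(
                    raster_dir / f"first_recovery_k_{name}.asc",
                    ledgers[name].first_k_map.astype(float), grid,
                )
        manifest = {
            "config": config.to_dict(),
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "input_checksums": {"occurrences.csv": _sha256(occ_path)},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

        return RunResult(
            config=config,
            outdir=outdir,
            stack=stack,
            presences=presences,
            kept_variables=kept2,
            dropped_correlated=dropped_corr,
            dropped_contribution=dropped_contrib,
            importance=importance,
            block_size_deg=block_size,
            cv=cv,
            suitability_peak=peak,
            threshold=threshold,
            present_binary=present_bin,
            scenario_losses=scenario_losses,
            family=family,
            ledgers=ledgers,
            metrics=metrics,
        )
    except Exception as exc:
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def report(ledgers: dict[str, RecoveryLedger], losses: dict[str, LossResult]) -> pd.DataFrame:
    """Tabular ledger: one row per scenario x tolerance target."""
    rows = []
    for name, ledger in ledgers.items():
        loss = losses[name]
        for k in ledger.k_values:
            rows.append(
                {
                    "scenario": name,
                    "k": k,
                    "present_suitable_km2": loss.present_area_km2,
                    "lost_km2": loss.lost_area_km2,
                    "contraction_pct": loss.contraction_pct,
                    "incremental_recovered_km2": ledger.incremental_recovered_km2[k],
                    "cumulative_recovered_km2": ledger.cumulative_recovered_km2[k],
                    "cumulative_recovered_pct": ledger.cumulative_recovered_pct[k],
                    "unrecovered_km2": ledger.unrecovered_km2,
                    "min_suitable_lat_east": loss.basin_min_suitable_lat.get("east"),
                    "min_suitable_lat_west": loss.basin_min_suitable_lat.get("west"),
                }
            )
    return pd.DataFrame(rows)
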