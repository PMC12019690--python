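"""Spatial block cross-validation, evaluation metrics, and model selection.

Validation folds are contiguous square spatial blocks so spatial
autocorrelation does not leak information between training and testing. The
block edge is chosen from an empirical correlogram of the temperature layer
(the distance at which autocorrelation first falls below 0.1); blocks are
dealt round-robin into k folds after a seeded shuffle. Hyperparameters are
chosen to minimize the train-test AUC gap, the standard overfitting guard
for presence-background models; the final suitability surface is the mean of
the k fold sub-models' cloglog maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .grid import GridSpec
from .maxnet import MaxNet
from .occurrences import GriddedOccurrences
from .stack import EnvStack

logger = logging.getLogger("kelpshift.blockcv")

__all__ = [
    "BlockFolds",
    "EvalMetrics",
    "auc",
    "tss",
    "choose_block_size",
    "assign_folds",
    "make_folds_with_presences",
    "cross_validate",
    "CVResult",
    "ensemble_map",
    "ensemble_response_curve",
]


@dataclass
class BlockFolds:
    """Checkerboard of square blocks dealt into k folds.

    ``fold_grid`` holds fold ids 1..k on valid cells and 0 elsewhere;
    ``block_grid`` holds a unique integer block id per cell.
    """

    grid: GridSpec
    block_size_deg: float
    block_grid: np.ndarray
    fold_grid: np.ndarray
    k: int
    seed: int

    def fold_of_cells(self, rows, cols) -> np.ndarray:
        return self.fold_grid[rows, cols]


@dataclass
class EvalMetrics:
    """Per-fold and mean discrimination metrics of the chosen model."""

    auc_train: list[float]
    auc_test: list[float]
    tss_test: list[float] = field(default_factory=list)
    tss_threshold: float | None = None

    @property
    def mean_auc_train(self) -> float:
        return float(np.mean(self.auc_train))

    @property
    def mean_auc_test(self) -> float:
        return float(np.mean(self.auc_test))

    @property
    def mean_tss_test(self) -> float:
        return float(np.mean(self.tss_test)) if self.tss_test else float("nan")

    def to_frame(self) -> pd.DataFrame:
        data = {"fold": np.arange(1, len(self.auc_train) + 1), "auc_train": self.auc_train, "auc_test": self.auc_test}
        if self.tss_test:
            data["tss_test"] = self.tss_test
        return pd.DataFrame(data)


def auc(positive_scores, negative_scores) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def tss(predicted_suitable, labels) -> float:
    """True Skill Statistic = sensitivity + specificity - 1 at a fixed
    binarization, background cells treated as absences."""
    pred = np.asarray(predicted_suitable, dtype=bool)
    y = np.asarray(labels, dtype=int)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("need both presence and background labels")
    sens = pred[y == 1].mean()
    spec = (~pred[y == 0]).mean()
    return float(sens + spec - 1.0)


def choose_block_size(
    layer: np.ndarray,
    grid: GridSpec,
    candidates: Sequence[float],
    seed: int = 0,
    mask: np.ndarray | None = None,
    n_sample: int = 2000,
    n_bins: int = 25,
    cutoff: float = 0.1,
) -> float:
    """Pick a block edge (degrees) from the layer's empirical correlogram.

    A Moran-type autocorrelation is computed at binned pair distances on a
    seeded sample of valid cells; the chosen size is the smallest candidate
    at least as large as the first distance where autocorrelation drops below
    ``cutoff``. If no candidate qualifies the largest is returned with a
    warning.
    """
    if len(candidates) < 2:
        if len(candidates) == 1:
            return float(candidates[0])
        raise ValueError("need at least one candidate block size")
    valid = np.isfinite(layer) if mask is None else (np.asarray(mask, dtype=bool) & np.isfinite(layer))
    rows, cols = np.nonzero(valid)
    if rows.size < 100:
        raise ValueError(f"need at least 100 valid cells to build a correlogram, got {rows.size}")
    rng = np.random.default_rng(seed)
    if rows.size > n_sample:
        idx = rng.choice(rows.size, n_sample, replace=False)
        rows, cols = rows[idx], cols[idx]
    lon, lat = grid.cell_center(rows, cols)
    values = layer[rows, cols]
    z = values - values.mean()
    var = z.var()
    if var <= 0:
        return float(min(candidates))

    dist = pdist(np.column_stack([lon, lat]))
    prod = squareform(np.outer(z, z) / var, checks=False)
    max_lag = 2.0 * max(candidates)
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(dist, edges) - 1
    corr = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.sum() >= 30:
            corr[b] = prod[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    below = np.nonzero(np.isfinite(corr) & (corr < cutoff))[0]
    if below.size == 0:
        logger.warning("choose_block_size: autocorrelation never fell below %.2f; using largest candidate", cutoff)
        return float(max(candidates))
    d_star = float(centers[below[0]])
    qualifying = [c for c in candidates if c >= d_star]
    if not qualifying:
        logger.warning("choose_block_size: no candidate >= correlogram range %.3f deg; using largest", d_star)
        return float(max(candidates))
    chosen = float(min(qualifying))
    logger.info("choose_block_size: correlogram range %.3f deg -> block %.3f deg", d_star, chosen)
    return chosen


def assign_folds(
    grid: GridSpec,
    mask: np.ndarray,
    block_size_deg: float,
    k: int = 5,
    seed: int = 0,
) -> BlockFolds:
    """Deal a checkerboard of square blocks round-robin into k folds (seeded)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if block_size_deg < grid.resolution:
        raise ValueError("block size must be at least one cell")
    mask = np.asarray(mask, dtype=bool)
    bs = max(1, int(round(block_size_deg / grid.resolution)))
    rr, cc = np.meshgrid(np.arange(grid.n_rows) // bs, np.arange(grid.n_cols) // bs, indexing="ij")
    n_block_cols = grid.n_cols // bs + 1
    block_grid = rr * n_block_cols + cc
    blocks = np.unique(block_grid[mask])
    if blocks.size < k:
        raise ValueError(f"only {blocks.size} blocks with valid cells; cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(blocks)
    fold_of_block = {int(b): (i % k) + 1 for i, b in enumerate(order)}
    fold_grid = np.zeros(grid.shape, dtype=int)
    for b, f in fold_of_block.items():
        fold_grid[(block_grid == b) & mask] = f
    return BlockFolds(grid=grid, block_size_deg=block_size_deg, block_grid=block_grid, fold_grid=fold_grid, k=k, seed=seed)


def make_folds_with_presences(
    grid: GridSpec,
    mask: np.ndarray,
    presences: GriddedOccurrences,
    block_size_deg: float,
    k: int = 5,
    seed: int = 0,
    max_tries: int = 20,
) -> BlockFolds:
    """Fold assignment that retries with an incremented seed (logged) until
    every fold contains at least one presence cell."""
    for attempt in range(max_tries):
        folds = assign_folds(grid, mask, block_size_deg, k=k, seed=seed + attempt)
        pres_folds = folds.fold_of_cells(presences.rows, presences.cols)
        if len(np.unique(pres_folds[pres_folds > 0])) == k:
            if attempt:
                logger.info("make_folds_with_presences: re-seeded %d time(s) to cover all folds", attempt)
            return folds
    raise RuntimeError(f"could not place presences in all {k} folds within {max_tries} re-seeds")


@dataclass
class CVResult:
    """Outcome of block cross-validation at the chosen hyperparameters."""

    chosen: tuple[str, float]  # (feature classes, beta multiplier)
    fits: list[MaxNet]  # one sub-model per fold (trained without that fold)
    metrics: EvalMetrics
    mean_map: np.ndarray  # mean cloglog over valid cells, NaN elsewhere
    folds: BlockFolds
    candidate_table: pd.DataFrame
    background_rows: np.ndarray
    background_cols: np.ndarray


def _candidate_sort_key(classes: str) -> int:
    return len(classes)


def select_candidate(table: pd.DataFrame) -> tuple[str, float]:
    """Apply the selection rule to a per-candidate metric table.

    Minimizes mean (AUC_train - AUC_test); ties broken by higher mean
    AUC_test, then by fewer feature classes. Table columns: classes,
    multiplier, mean_auc_train, mean_auc_test.
    """
    table = table.copy()
    table["gap"] = table["mean_auc_train"] - table["mean_auc_test"]
    table = table.sort_values(
        by=["gap", "mean_auc_test", "n_classes"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    row = table.iloc[0]
    return str(row["classes"]), float(row["multiplier"])


def cross_validate(
    presences: GriddedOccurrences,
    stack: EnvStack,
    folds: BlockFolds,
    candidates: Sequence[tuple[str, float]] = (("l", 1.0), ("lq", 1.0), ("lqp", 1.0)),
    background_cap: int = 50_000,
    seed: int = 0,
) -> CVResult:
    """Blocked k-fold fitting, hyperparameter choice, and map averaging.

    For each candidate ``(feature classes, beta multiplier)``, k sub-models
    are trained on k-1 folds of presence and background cells and tested on
    the held-out fold (background inherits fold membership from its cells).
    The candidate minimizing the mean train-test AUC gap wins; the final
    suitability map is the mean of the k winning sub-models' cloglog maps
    over all valid cells.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    rows_bg, cols_bg = stack.valid_cells()
    if rows_bg.size > background_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(rows_bg.size, background_cap, replace=False)
        rows_bg, cols_bg = rows_bg[idx], cols_bg[idx]
    pres_fold = folds.fold_of_cells(presences.rows, presences.cols)
    bg_fold = folds.fold_of_cells(rows_bg, cols_bg)
    if np.any(pres_fold == 0):
        raise ValueError("some presence cells fall outside the fold partition (masked cells?)")

    X_pres = stack.table(presences.rows, presences.cols)
    X_bg = stack.table(rows_bg, cols_bg)
    X_all = pd.concat([X_pres, X_bg], ignore_index=True)
    y_all = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_bg))])
    fold_all = np.concatenate([pres_fold, bg_fold])

    records = []
    fits_by_candidate: dict[tuple[str, float], list[MaxNet]] = {}
    aucs_by_candidate: dict[tuple[str, float], tuple[list[float], list[float]]] = {}
    for classes, mult in candidates:
        fits: list[MaxNet] = []
        auc_tr: list[float] = []
        auc_te: list[float] = []
        for f in range(1, folds.k + 1):
            test = fold_all == f
            train = ~test
            if not np.any((y_all == 1) & test):
                raise ValueError(f"fold {f} has no test presences; re-seed the folds")
            est = MaxNet(feature_classes=classes, beta_multiplier=mult)
            with np.errstate(over="ignore"):
                est.fit(X_all[train], y_all[train])
            s_train = est.predict(X_all[train], output="raw")
            s_test = est.predict(X_all[test], output="raw")
            y_tr, y_te = y_all[train], y_all[test]
            auc_tr.append(auc(s_train[y_tr == 1], s_train[y_tr == 0]))
            auc_te.append(auc(s_test[y_te == 1], s_test[y_te == 0]))
            fits.append(est)
        records.append(
            {
                "classes": classes,
                "multiplier": mult,
                "n_classes": _candidate_sort_key(classes),
                "mean_auc_train": float(np.mean(auc_tr)),
                "mean_auc_test": float(np.mean(auc_te)),
            }
        )
        fits_by_candidate[(classes, mult)] = fits
        aucs_by_candidate[(classes, mult)] = (auc_tr, auc_te)
        logger.info(
            "cross_validate: candidate %s x %.2g -> train %.3f test %.3f",
            classes, mult, records[-1]["mean_auc_train"], records[-1]["mean_auc_test"],
        )

    table = pd.DataFrame(records)
    chosen = select_candidate(table)
    fits = fits_by_candidate[chosen]
    auc_tr, auc_te = aucs_by_candidate[chosen]
    metrics = EvalMetrics(auc_train=auc_tr, auc_test=auc_te)
    mean_map = ensemble_map(fits, stack)
    logger.info("cross_validate: chose %s (gap %.4f)", chosen, metrics.mean_auc_train - metrics.mean_auc_test)
    return CVResult(
        chosen=chosen,
        fits=fits,
        metrics=metrics,
        mean_map=mean_map,
        folds=folds,
        candidate_table=table,
        background_rows=rows_bg,
        background_cols=cols_bg,
    )


def ensemble_response_curve(
    fits: Sequence[MaxNet],
    variable: str,
    n_points: int = 200,
    bounds: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean cloglog response of an ensemble along one variable.

    Sub-models are evaluated on a shared variable grid (the union of their
    training ranges unless ``bounds`` is given), each holding its other
    variables at its own background means; per-model clamping applies as at
    prediction time. Averaging on a shared grid matters: fold sub-models see
    different training ranges, and averaging curves defined on different
    grids would warp the curve and bias its argmax.
    """
    if bounds is None:
        i = fits[0].variables_.index(variable)
        los, his = zip(*[(f.feature_spec_.clamp_bounds[i]) for f in fits])
        bounds = (min(los), max(his))
    grid = np.linspace(bounds[0], bounds[1], n_points)
    acc = np.zeros(n_points)
    for est in fits:
        data = {v: np.full(n_points, est.background_means_[v]) for v in est.variables_}
        data[variable] = grid
        acc += est.predict(pd.DataFrame(data), output="cloglog")
    return grid, acc / len(fits)


def ensemble_map(fits: Sequence[MaxNet], stack: EnvStack) -> np.ndarray:
    """Mean cloglog suitability of an ensemble over a stack's valid cells."""
    rows, cols = stack.valid_cells()
    X = stack.table(rows, cols, variables=fits[0].variables_)
    acc = np.zeros(rows.size)
    for est in fits:
        acc += est.predict(X, output="cloglog")
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = acc / len(fits)
    return out
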