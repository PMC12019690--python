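"""Simulated increases in upper thermal tolerance via a logistic layer warp.

A flat +k degC added to every cell above the thermal optimum would tear the
temperature field (missing values between the old and new warm tail) and
produce a disjointed response curve. Instead the training temperature layer
is warped additively with a logistic ramp

    delta(x) = T_inc / (1 + exp(-r * (x - p)))

where ``p`` is the suitability peak (thermal optimum of the base model's
response curve), ``r`` the transition steepness (per degC), and ``T_inc``
the asymptotic increment. The warped layer ``x + delta(x)`` is strictly
increasing in ``x`` — no rank inversions, no gaps — and cold cells are left
essentially untouched while the warm tail is stretched upward, so a model
retrained on it expresses an upper-tolerance gain of ``k`` degC once
``T_inc`` is calibrated so the retrained response curve's upper threshold
crossing sits ``k`` degC above the base model's.

Occurrences are never moved, and projections always use unmodified scenario
layers; only the training temperature layer changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit

logger = logging.getLogger("kelpshift.tolerance")

__all__ = [
    "ToleranceTransform",
    "delta",
    "transform_layer",
    "upper_crossing",
    "calibrate_Tinc",
    "ShiftedEnsemble",
    "shifted_capture_threshold",
    "train_shifted_family",
]


@dataclass(frozen=True)
class ToleranceTransform:
    """Parameters of the logistic temperature warp for one tolerance target.

    ``target_increase`` k is the intended upper-tolerance gain (integer degC,
    1-5); ``temperature_increase`` T_inc is the asymptotic increment (>= k,
    species and k specific); ``increase_rate`` r sets the steepness of the
    transition around the ``suitability_peak`` p.
    """

    target_increase: int
    temperature_increase: float
    increase_rate: float = 2.0
    suitability_peak: float = 0.0

    def __post_init__(self) -> None:
        if self.target_increase < 1:
            raise ValueError("target_increase must be >= 1")
        if self.temperature_increase < self.target_increase:
            raise ValueError("temperature_increase must be >= target_increase")
        if self.increase_rate <= 0:
            raise ValueError("increase_rate must be positive")


def delta(x, t: ToleranceTransform):
    """Logistic increment ``T_inc / (1 + exp(-r (x - p)))``; in (0, T_inc),
    strictly increasing, exactly ``T_inc / 2`` at the suitability peak."""
    x = np.asarray(x, dtype=float)
    out = t.temperature_increase * expit(t.increase_rate * (x - t.suitability_peak))
    return float(out) if out.ndim == 0 else out


def transform_layer(layer: np.ndarray, t: ToleranceTransform) -> np.ndarray:
    """Cell-wise ``x + delta(x)``; NaN (masked) cells preserved."""
    layer = np.asarray(layer, dtype=float)
    out = layer + delta(layer, t)
    return out


def upper_crossing(temps: np.ndarray, values: np.ndarray, threshold: float) -> float:
    """Temperature where a response curve last falls through ``threshold`` on
    its upper (warm) tail, linearly interpolated between curve points."""
    temps = np.asarray(temps, dtype=float)
    values = np.asarray(values, dtype=float)
    above = values >= threshold
    if not above.any():
        raise ValueError("response curve never reaches the threshold")
    last = int(np.nonzero(above)[0][-1])
    if last == temps.size - 1:
        raise ValueError("response curve does not cross the threshold on its upper tail")
    t0, t1 = temps[last], temps[last + 1]
    v0, v1 = values[last], values[last + 1]
    if v0 == v1:
        return float(t0)
    return float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))


def calibrate_Tinc(
    curve_temps: np.ndarray,
    curve_values: np.ndarray,
    threshold: float,
    k: int,
    r: float,
    peak: float,
    retrain: Callable[[float], tuple[np.ndarray, np.ndarray]] | None = None,
    tol: float = 0.05,
    max_iter: int = 14,
) -> float:
    """Calibrate the asymptotic increment so the warp yields a +k degC gain.

    The gain is measured at the binarization threshold: the calibrated warp
    should move the response curve's upper threshold crossing ``k`` degC
    upward. In full mode (``retrain`` given: maps a trial T_inc to the
    retrained model's response curve) the value is found by bisection on
    ``T_inc in [k, k + 10]`` to within ``tol`` degC of crossing offset. In
    fast mode (``retrain is None``) the first-order value is returned: the
    warp moves the crossing by ``delta(x_cross)``, so
    ``T_inc = k * (1 + exp(-r * (x_cross - p)))``.
    """
    if k < 1:
        raise ValueError("target_increase must be >= 1")
    x_cross = upper_crossing(curve_temps, curve_values, threshold)
    if retrain is None:
        t_inc = k * (1.0 + np.exp(-r * (x_cross - peak)))
        logger.info("calibrate_Tinc[fast]: k=%d x_cross=%.3f -> T_inc=%.3f", k, x_cross, t_inc)
        return float(t_inc)

    def offset(t_inc: float) -> float:
        out = retrain(t_inc)
        # retrain may supply its own operational threshold (e.g. the
        # retrained model's occurrence-capture threshold) as a third element
        temps_k, vals_k = out[0], out[1]
        thresh_k = out[2] if len(out) > 2 else threshold
        return upper_crossing(temps_k, vals_k, thresh_k) - x_cross - k

    lo, hi = float(k), float(k + 10)
    f_lo, f_hi = offset(lo), offset(hi)
    if f_lo >= 0:
        logger.info("calibrate_Tinc[full]: k=%d satisfied at lower bound T_inc=%.3f", k, lo)
        return lo
    if f_hi <= 0:
        logger.warning("calibrate_Tinc[full]: k=%d not bracketed at T_inc=%.1f; returning upper bound", k, hi)
        return hi
    mid = lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = offset(mid)
        if abs(f_mid) <= tol:
            break
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    logger.info("calibrate_Tinc[full]: k=%d -> T_inc=%.3f", k, mid)
    return float(mid)


# -------------------------------------------------- shifted model families


@dataclass
class ShiftedEnsemble:
    """A tolerance-k ensemble: the warp used and the refitted fold models."""

    transform: "ToleranceTransform"
    fits: list  # one MaxNet per fold, trained on the warped present layer


def shifted_capture_threshold(ensemble: "ShiftedEnsemble", stack, presences, capture: float = 0.95) -> float:
    """Binarization threshold of a tolerance-k ensemble.

    The 95%-capture rule is applied exactly as for the base model: occurrence
    cells are scored in the model's own training environment, which for a
    shifted model is the warped present temperature layer.
    """
    from .ranges import capture_threshold
    from .stack import TEMPERATURE

    warped = stack.with_layer(
        TEMPERATURE, transform_layer(stack.layers[TEMPERATURE], ensemble.transform)
    )
    X_occ = warped.table(presences.rows, presences.cols)
    mean_suit = np.mean(
        [est.predict(X_occ, output="cloglog") for est in ensemble.fits], axis=0
    )
    return capture_threshold(mean_suit, capture=capture)


def train_shifted_family(
    presences,
    stack,
    folds,
    chosen: tuple[str, float],
    base_curve: tuple[np.ndarray, np.ndarray],
    threshold: float,
    peak: float,
    k_list=(1, 2, 3, 4, 5),
    increase_rate: float = 2.0,
    calibration: str = "full",
    background_rows: np.ndarray | None = None,
    background_cols: np.ndarray | None = None,
    curve_points: int = 200,
    capture: float = 0.95,
) -> dict[int, ShiftedEnsemble]:
    """Train the +1..+k degC tolerance model family.

    For each target increase k the present temperature layer is warped with
    a calibrated :class:`ToleranceTransform`, and the fold sub-models are
    refitted with identical folds, hyperparameters, and non-temperature
    layers. Fit failures for one k are logged and the remaining targets
    continue. Projection of the returned ensembles must use unmodified
    scenario layers.

    ``calibration`` is "full" (bisection with retraining, the default) or
    "fast" (closed-form first-order value).
    """
    from .maxnet import MaxNet
    from .stack import TEMPERATURE

    for k in k_list:
        if int(k) != k or k < 1:
            raise ValueError("target_increase must be >= 1 (integer)")
    classes, mult = chosen
    if background_rows is None:
        background_rows, background_cols = stack.valid_cells()
    X_pres_idx = (presences.rows, presences.cols)
    y = np.concatenate([np.ones(presences.rows.size), np.zeros(background_rows.size)])
    fold_all = np.concatenate(
        [folds.fold_of_cells(*X_pres_idx), folds.fold_of_cells(background_rows, background_cols)]
    )
    rows_all = np.concatenate([presences.rows, background_rows])
    cols_all = np.concatenate([presences.cols, background_cols])

    from .blockcv import ensemble_response_curve
    from .ranges import capture_threshold

    def fit_fold_ensemble(warped_stack) -> list:
        X_all = warped_stack.table(rows_all, cols_all)
        fits = []
        for f in range(1, folds.k + 1):
            train = fold_all != f
            est = MaxNet(feature_classes=classes, beta_multiplier=mult)
            with np.errstate(over="ignore"):
                est.fit(X_all[train], y[train])
            fits.append(est)
        return fits

    def occ_capture_threshold(fits, warped_stack) -> float:
        X_occ = warped_stack.table(presences.rows, presences.cols)
        mean_suit = np.mean([est.predict(X_occ, output="cloglog") for est in fits], axis=0)
        return capture_threshold(mean_suit, capture=capture)

    curve_temps, curve_values = base_curve
    out: dict[int, ShiftedEnsemble] = {}
    for k in k_list:
        k = int(k)
        try:
            # calibration retrains the operational object -- the fold
            # ensemble -- and reads its curve at its own occurrence-capture
            # threshold, exactly as binarization will downstream
            cache: dict[float, tuple[ToleranceTransform, list]] = {}

            def retrain(t_inc: float, _k=k):
                t = ToleranceTransform(_k, t_inc, increase_rate, peak)
                warped = stack.with_layer(TEMPERATURE, transform_layer(stack.layers[TEMPERATURE], t))
                fits = fit_fold_ensemble(warped)
                cache[t_inc] = (t, fits)
                temps_k, vals_k = ensemble_response_curve(fits, TEMPERATURE, n_points=curve_points)
                return temps_k, vals_k, occ_capture_threshold(fits, warped)

            t_inc = calibrate_Tinc(
                curve_temps,
                curve_values,
                threshold,
                k,
                increase_rate,
                peak,
                retrain=retrain if calibration == "full" else None,
            )
            if t_inc in cache:
                t, fits = cache[t_inc]
            else:
                t = ToleranceTransform(k, t_inc, increase_rate, peak)
                warped = stack.with_layer(TEMPERATURE, transform_layer(stack.layers[TEMPERATURE], t))
                fits = fit_fold_ensemble(warped)
            out[k] = ShiftedEnsemble(transform=t, fits=fits)
        except Exception:  # propagate per-k failures as a summary, not an abort
            logger.exception("train_shifted_family: k=%d failed; continuing", k)
    failed = sorted(set(int(k) for k in k_list) - set(out))
    if failed:
        logger.warning("train_shifted_family: failed for k=%s", failed)
    return out
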