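"""Presence-background MaxEnt model (maxnet-style penalized Gibbs fit).

The model estimates the maximum-entropy distribution over environmental
feature space consistent with the presence sample: a Gibbs density
``raw(z) = exp(f(z) . beta) / Z`` over the background cells, fitted by
maximizing the L1-penalized presence log-likelihood

    (1/m) sum_presence f(x) . beta  -  log sum_background exp(f(z) . beta)
    -  sum_j lambda_j |beta_j|

with per-feature penalties ``lambda_j = multiplier * r(class_j, m) *
scale_j / sqrt(m)`` following the published MaxEnt default schedule (shipped
as a JSON table, overridable). Features are linear, quadratic, and pairwise
product expansions of the raw variables; prediction-time inputs are clamped
into the training range. The "cloglog" output ``1 - exp(-exp(H) * raw)``
maps the raw density into (0, 1) using the entropy H of the fitted
distribution over the training background.

The solver is cyclic coordinate descent with soft-thresholding on a local
quadratic model of the smooth part, safeguarded by step halving so the
penalized objective never increases.

:class:`MaxNet` is a scikit-learn style estimator: ``fit(X, y)`` with X the
raw environmental variables at presence (y=1) and background (y=0) points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureSpec",
    "MaxNet",
    "build_features",
    "fit_maxnet",
    "predict",
    "response_curve",
    "permutation_importance",
    "default_regularization",
    "fit_penalized",
]

FEATURE_CLASS_ALIASES = {"l": "linear", "q": "quadratic", "p": "product"}
VALID_CLASSES = frozenset(FEATURE_CLASS_ALIASES.values())


def _normalize_classes(classes) -> tuple[str, ...]:
    """Accept {'linear','quadratic'}, 'lqp', or ['l','q'] spellings."""
    if isinstance(classes, str):
        classes = list(classes) if set(classes) <= set("lqp") else [classes]
    out = []
    for c in classes:
        c = FEATURE_CLASS_ALIASES.get(c.lower(), c.lower())
        if c not in VALID_CLASSES:
            raise ValueError(f"unknown feature class {c!r}; valid: {sorted(VALID_CLASSES)}")
        if c not in out:
            out.append(c)
    if not out:
        raise ValueError("feature classes must be non-empty")
    return tuple(sorted(out, key=["linear", "quadratic", "product"].index))


@dataclass(frozen=True)
class FeatureSpec:
    """Deterministic feature expansion of raw variables.

    Columns are ordered: linear terms in alphabetical variable order, then
    quadratic terms, then products of unordered distinct pairs (alphabetical).
    ``clamp_bounds`` are the per-variable training min/max applied to
    prediction-time inputs only.
    """

    variables: tuple[str, ...]
    classes: tuple[str, ...]
    clamp_bounds: tuple[tuple[float, float], ...] = ()

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        if "linear" in self.classes:
            names += list(self.variables)
        if "quadratic" in self.classes:
            names += [f"{v}^2" for v in self.variables]
        if "product" in self.classes:
            names += [f"{a}*{b}" for a, b in combinations(self.variables, 2)]
        return names

    @property
    def feature_classes(self) -> list[str]:
        classes: list[str] = []
        if "linear" in self.classes:
            classes += ["linear"] * len(self.variables)
        if "quadratic" in self.classes:
            classes += ["quadratic"] * len(self.variables)
        if "product" in self.classes:
            classes += ["product"] * (len(self.variables) * (len(self.variables) - 1) // 2)
        return classes

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _as_variable_matrix(X, variables: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        variables = tuple(sorted(X.columns)) if variables is None else tuple(variables)
        return X.loc[:, list(variables)].to_numpy(dtype=float), variables
    if isinstance(X, Mapping):
        variables = tuple(sorted(X)) if variables is None else tuple(variables)
        return np.column_stack([np.asarray(X[v], dtype=float) for v in variables]), variables
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if variables is None:
        variables = tuple(f"x{i}" for i in range(X.shape[1]))
    return X, tuple(variables)


def build_features(X, spec: FeatureSpec, clamp: bool = False) -> np.ndarray:
    """Expand raw variables into the model's feature matrix.

    ``clamp=True`` (prediction time) clips each raw variable into the spec's
    training bounds before expansion, so extrapolated cells behave like the
    nearest training condition.
    """
    V, variables = _as_variable_matrix(X, spec.variables)
    if V.shape[1] != len(spec.variables):
        raise ValueError(f"expected {len(spec.variables)} variables {spec.variables}, got {V.shape[1]}")
    if clamp:
        if not spec.clamp_bounds:
            raise ValueError("spec carries no clamp bounds (unfitted?)")
        lo = np.array([b[0] for b in spec.clamp_bounds])
        hi = np.array([b[1] for b in spec.clamp_bounds])
        V = np.clip(V, lo, hi)
    blocks = []
    if "linear" in spec.classes:
        blocks.append(V)
    if "quadratic" in spec.classes:
        blocks.append(V**2)
    if "product" in spec.classes:
        pairs = list(combinations(range(V.shape[1]), 2))
        if pairs:
            blocks.append(np.column_stack([V[:, i] * V[:, j] for i, j in pairs]))
    if not blocks:
        return np.empty((V.shape[0], 0))
    return np.concatenate(blocks, axis=1)


def default_regularization(feature_classes: Sequence[str], scales: np.ndarray, m: int, multiplier: float = 1.0, table: dict | None = None) -> np.ndarray:
    """Per-feature L1 weights: ``multiplier * r(class, m) * scale / sqrt(m)``.

    ``r`` interpolates the shipped MaxEnt default table in the presence count
    ``m`` (clamped at the table ends).
    """
    if table is None:
        with resources.files("kelpshift.data").joinpath("maxent_regularization.json").open() as fh:
            table = json.load(fh)
    lam = np.empty(len(feature_classes))
    for j, cls in enumerate(feature_classes):
        entry = table[cls]
        r = np.interp(m, entry["n_presences"], entry["r"])
        lam[j] = multiplier * r * scales[j] / np.sqrt(m)
    return lam


def penalized_objective(beta: np.ndarray, P: np.ndarray, B: np.ndarray, lam: np.ndarray) -> float:
    """Negative penalized presence log-likelihood (the quantity minimized)."""
    eta_p = P @ beta
    eta_b = B @ beta
    return float(-eta_p.mean() + logsumexp(eta_b) + np.sum(lam * np.abs(beta)))


def _lbfgs_warm_start(P: np.ndarray, B: np.ndarray, lam: np.ndarray, beta0: np.ndarray | None = None) -> np.ndarray:
    """Approximate minimizer via the split-variable (beta = b+ - b-) bound-
    constrained reformulation, which turns the L1 term into a linear one."""
    from scipy.optimize import minimize

    p_mean = P.mean(axis=0)
    n_feat = B.shape[1]

    def fun_grad(z):
        beta = z[:n_feat] - z[n_feat:]
        eta_b = B @ beta
        lse = logsumexp(eta_b)
        w = np.exp(eta_b - lse)
        g = -p_mean + w @ B
        val = float(-(P @ beta).mean() + lse + lam @ (z[:n_feat] + z[n_feat:]))
        grad = np.concatenate([g + lam, -g + lam])
        return val, grad

    z0 = np.zeros(2 * n_feat)
    if beta0 is not None:
        z0[:n_feat] = np.maximum(beta0, 0.0)
        z0[n_feat:] = np.maximum(-beta0, 0.0)
    res = minimize(
        fun_grad,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * n_feat),
        options={"maxiter": 5000, "maxfun": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x[:n_feat] - res.x[n_feat:]


def fit_penalized(
    P: np.ndarray,
    B: np.ndarray,
    lam: np.ndarray,
    max_iter: int = 2000,
    tol_objective: float = 1e-8,
    tol_coef: float = 1e-6,
    warm_start: bool = True,
) -> tuple[np.ndarray, list[float]]:
    """Minimize the penalized objective.

    A split-variable quasi-Newton phase supplies a warm start (the
    near-collinear quadratic/product features make the problem too
    ill-conditioned for plain coordinate descent from zero); safeguarded
    cyclic coordinate descent with soft-thresholding then finishes. Each
    coordinate step is halved until it does not increase the objective, so
    the returned objective path is non-increasing by construction. Raises on
    hitting the sweep cap without meeting either tolerance.
    """
    P = np.asarray(P, dtype=float)
    B = np.asarray(B, dtype=float)
    lam = np.asarray(lam, dtype=float)
    n_feat = B.shape[1]
    beta = np.zeros(n_feat)
    eta_b = B @ beta
    eta_p = P @ beta
    p_mean = P.mean(axis=0)

    def objective() -> float:
        return float(-eta_p.mean() + logsumexp(eta_b) + np.sum(lam * np.abs(beta)))

    obj = objective()
    path = [obj]
    max_rounds = 3 if warm_start and n_feat else 1
    for round_no in range(max_rounds):
        if warm_start and n_feat:
            candidate = _lbfgs_warm_start(P, B, lam, beta0=beta if round_no else None)
            cand_obj = float(
                -(P @ candidate).mean() + logsumexp(B @ candidate) + np.sum(lam * np.abs(candidate))
            )
            if cand_obj <= obj:  # accept only a non-increasing hand-off
                beta = candidate
                eta_b = B @ beta
                eta_p = P @ beta
                obj = cand_obj
                path.append(obj)
        # early rounds get a short sweep budget before a quasi-Newton restart;
        # the final round may use the full cap
        budget = max_iter if round_no == max_rounds - 1 else min(100, max_iter)
        for _ in range(budget):
            max_step = 0.0
            for j in range(n_feat):
                # Gibbs weights over background under the current beta
                w = np.exp(eta_b - logsumexp(eta_b))
                bj = B[:, j]
                mu = w @ bj
                grad = -p_mean[j] + mu
                hess = max(w @ (bj * bj) - mu * mu, 1e-12)
                target = beta[j] * hess - grad
                proposal = np.sign(target) * max(abs(target) - lam[j], 0.0) / hess
                d = proposal - beta[j]
                if d == 0.0:
                    continue
                # step halving: never let the penalized objective increase
                for _ in range(40):
                    new_bj = beta[j] + d
                    new_eta_b = eta_b + d * bj
                    new_eta_p = eta_p + d * P[:, j]
                    new_obj = float(
                        -new_eta_p.mean()
                        + logsumexp(new_eta_b)
                        + np.sum(lam * np.abs(beta))
                        + lam[j] * (abs(new_bj) - abs(beta[j]))
                    )
                    if new_obj <= obj + 1e-14:
                        beta[j] = new_bj
                        eta_b = new_eta_b
                        eta_p = new_eta_p
                        obj = new_obj
                        max_step = max(max_step, abs(d))
                        break
                    d *= 0.5
            path.append(obj)
            if path[-2] - path[-1] < tol_objective or max_step < tol_coef:
                return beta, path
    raise RuntimeError(
        f"solver did not converge in {max_rounds} rounds of {max_iter} sweeps "
        f"(last objective change {path[-2] - path[-1]:.3e}, last max step {max_step:.3e})"
    )


class MaxNet(BaseEstimator):
    """Presence-background MaxEnt model as a scikit-learn estimator.

    Parameters
    ----------
    feature_classes : str or sequence, default "lqp"
        Any subset of linear / quadratic / product, also spellable as
        ``"l"``, ``"lq"``, ``"lqp"``.
    beta_multiplier : float, default 1.0
        Global multiplier on the default regularization schedule.
    clamp : bool, default True
        Clamp prediction-time inputs into the training range.
    reg_table : dict, optional
        Override of the shipped regularization schedule.

    Attributes
    ----------
    coef_ : ndarray, fitted feature coefficients (beta).
    lambda_ : ndarray, per-feature L1 weights.
    feature_spec_ : FeatureSpec with training clamp bounds.
    Z_ : float, background normalizer of the raw distribution.
    entropy_ : float, entropy H of the raw distribution over background.
    background_means_ : per-variable background means (response curves).
    n_presence_, n_background_ : training sample sizes.
    objective_path_ : penalized objective per solver sweep (non-increasing).
    """

    def __init__(
        self,
        feature_classes="lqp",
        beta_multiplier: float = 1.0,
        clamp: bool = True,
        max_iter: int = 2000,
        tol_objective: float = 1e-8,
        tol_coef: float = 1e-6,
        reg_table: dict | None = None,
    ):
        self.feature_classes = feature_classes
        self.beta_multiplier = beta_multiplier
        self.clamp = clamp
        self.max_iter = max_iter
        self.tol_objective = tol_objective
        self.tol_coef = tol_coef
        self.reg_table = reg_table

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        V, variables = _as_variable_matrix(X, None)
        y = np.asarray(y)
        if V.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        pres = y == 1
        bg = y == 0
        m = int(pres.sum())
        n_bg = int(bg.sum())
        if m < 5:
            raise ValueError(f"need at least 5 presence points, got {m}")
        if n_bg == 0:
            raise ValueError("need background points (y == 0)")
        if n_bg < 10 * m:
            warnings.warn(f"background ({n_bg}) smaller than 10x presences ({m}); estimates may be unstable")

        classes = _normalize_classes(self.feature_classes)
        lo = V.min(axis=0)
        hi = V.max(axis=0)
        spec = FeatureSpec(variables=variables, classes=classes, clamp_bounds=tuple(zip(lo, hi)))
        F = build_features(pd.DataFrame(V, columns=variables), spec)
        P, B = F[pres], F[bg]

        scales = B.std(axis=0)
        constant = scales <= 1e-12
        if constant.any():
            names = [n for n, c in zip(spec.feature_names, constant) if c]
            warnings.warn(f"constant features excluded from fitting: {names}")
        scales = np.where(constant, 1.0, scales)
        lam = default_regularization(spec.feature_classes, scales, m, self.beta_multiplier, self.reg_table)

        # Solve in the centered, unit-variance feature basis: the raw
        # distribution is invariant to constant shifts, and because lambda_j
        # is proportional to the feature scale the standardized problem has a
        # uniform penalty and far better conditioning. beta maps back by 1/sd.
        center = B.mean(axis=0)
        active = ~constant
        sd = scales[active]
        P_std = (P - center)[:, active] / sd
        B_std = (B - center)[:, active] / sd
        beta_std, path = fit_penalized(
            P_std, B_std, lam[active] / sd, self.max_iter, self.tol_objective, self.tol_coef
        )
        beta = np.zeros(F.shape[1])
        beta[active] = beta_std / sd
        lam = np.where(constant, np.inf, lam)  # constants are pinned at 0

        eta_b = (B - center) @ beta
        log_z = logsumexp(eta_b)
        log_raw = eta_b - log_z
        raw = np.exp(log_raw)

        self.variables_ = variables
        self.feature_spec_ = spec
        self.coef_ = beta
        self.lambda_ = lam
        self.feature_center_ = center
        self.Z_ = float(np.exp(log_z))
        self.log_Z_ = float(log_z)
        self.entropy_ = float(-np.sum(raw * log_raw))
        self.background_means_ = dict(zip(variables, V[bg].mean(axis=0)))
        self.n_presence_ = m
        self.n_background_ = n_bg
        self.objective_path_ = path
        self.n_features_in_ = len(variables)
        return self

    # -------------------------------------------------------------- predict
    def _eta(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        F = build_features(X, self.feature_spec_, clamp=self.clamp)
        if F.shape[1] != self.coef_.size:
            raise ValueError(f"feature count mismatch: got {F.shape[1]}, model has {self.coef_.size}")
        return (F - self.feature_center_) @ self.coef_

    def decision_function(self, X) -> np.ndarray:
        """Linear score ``f(x) . beta`` (centered); monotone in suitability."""
        return self._eta(X)

    def predict(self, X, output: str = "cloglog") -> np.ndarray:
        """Suitability per point: ``raw`` Gibbs density (sums to 1 over the
        training background) or its ``cloglog`` transform in (0, 1)."""
        eta = self._eta(X)
        raw = np.exp(eta - self.log_Z_)
        if output == "raw":
            return raw
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy_) * raw)
        raise ValueError(f"unknown output {output!r}; use 'raw' or 'cloglog'")

    # ---------------------------------------------------------- diagnostics
    def response_curve(self, variable: str, n_points: int = 200) -> tuple[np.ndarray, np.ndarray]:
        """cloglog suitability along one variable, others at background means.

        The variable sweeps its training range. Returns ``(grid, values)``;
        use :func:`response_peak` or ``grid[values.argmax()]`` for the
        optimum (ties resolve to the lowest value of the variable).
        """
        check_is_fitted(self, "coef_")
        if variable not in self.variables_:
            raise KeyError(f"variable {variable!r} not in model variables {self.variables_}")
        i = self.variables_.index(variable)
        lo, hi = self.feature_spec_.clamp_bounds[i]
        grid = np.linspace(lo, hi, n_points)
        data = {v: np.full(n_points, self.background_means_[v]) for v in self.variables_}
        data[variable] = grid
        values = self.predict(pd.DataFrame(data), output="cloglog")
        return grid, values

    def response_peak(self, variable: str, n_points: int = 200) -> float:
        grid, values = self.response_curve(variable, n_points)
        return float(grid[int(np.argmax(values))])

    def permutation_importance(self, X, y, n_repeats: int = 5, seed: int = 0) -> pd.Series:
        """Percent contribution per variable (sums to 100).

        For each variable, its raw values are shuffled across all points
        (presence and background alike), features rebuilt, and the mean drop
        in training AUC over ``n_repeats`` measured; negative drops floor at
        0 and the drops are normalized to percentages.
        """
        from .blockcv import auc  # local import to avoid a cycle

        check_is_fitted(self, "coef_")
        if n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        V, variables = _as_variable_matrix(X, self.variables_)
        y = np.asarray(y)
        rng = np.random.default_rng(seed)
        base_scores = self.predict(pd.DataFrame(V, columns=variables), output="raw")
        base_auc = auc(base_scores[y == 1], base_scores[y == 0])
        drops = np.zeros(len(variables))
        for i in range(len(variables)):
            vals = []
            for _ in range(n_repeats):
                Vp = V.copy()
                Vp[:, i] = rng.permutation(Vp[:, i])
                scores = self.predict(pd.DataFrame(Vp, columns=variables), output="raw")
                vals.append(base_auc - auc(scores[y == 1], scores[y == 0]))
            drops[i] = max(float(np.mean(vals)), 0.0)
        if drops.sum() == 0:
            warnings.warn("all permutation drops are zero; returning uniform contributions")
            drops[:] = 1.0
        pct = 100.0 * drops / drops.sum()
        return pd.Series(pct, index=list(variables), name="contribution_pct")

    def to_json(self) -> str:
        """Serialize the fitted model for exact reload."""
        check_is_fitted(self, "coef_")
        payload = {
            "params": self.get_params(),
            "variables": list(self.variables_),
            "classes": list(self.feature_spec_.classes),
            "clamp_bounds": [list(b) for b in self.feature_spec_.clamp_bounds],
            "coef": self.coef_.tolist(),
            "lambda": [None if not np.isfinite(v) else v for v in self.lambda_],
            "feature_center": self.feature_center_.tolist(),
            "log_Z": self.log_Z_,
            "entropy": self.entropy_,
            "background_means": self.background_means_,
            "n_presence": self.n_presence_,
            "n_background": self.n_background_,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxNet":
        d = json.loads(text)
        est = cls(**d["params"])
        est.variables_ = tuple(d["variables"])
        est.feature_spec_ = FeatureSpec(
            variables=est.variables_,
            classes=tuple(d["classes"]),
            clamp_bounds=tuple(tuple(b) for b in d["clamp_bounds"]),
        )
        est.coef_ = np.asarray(d["coef"], dtype=float)
        est.lambda_ = np.array([np.inf if v is None else v for v in d["lambda"]])
        est.feature_center_ = np.asarray(d["feature_center"], dtype=float)
        est.log_Z_ = float(d["log_Z"])
        est.Z_ = float(np.exp(est.log_Z_))
        est.entropy_ = float(d["entropy"])
        est.background_means_ = dict(d["background_means"])
        est.n_presence_ = int(d["n_presence"])
        est.n_background_ = int(d["n_background"])
        est.objective_path_ = []
        est.n_features_in_ = len(est.variables_)
        return est


# ----------------------------------------------------------- thin wrappers


def fit_maxnet(presence, background, feature_classes="lqp", beta_multiplier: float = 1.0, **kwargs) -> MaxNet:
    """Fit a MaxNet model from separate presence / background variable tables."""
    P, variables = _as_variable_matrix(presence, None)
    B, _ = _as_variable_matrix(background, variables)
    X = pd.DataFrame(np.vstack([P, B]), columns=variables)
    y = np.concatenate([np.ones(P.shape[0]), np.zeros(B.shape[0])])
    return MaxNet(feature_classes=feature_classes, beta_multiplier=beta_multiplier, **kwargs).fit(X, y)


def predict(fit: MaxNet, X, output: str = "cloglog") -> np.ndarray:
    return fit.predict(X, output=output)


def response_curve(fit: MaxNet, variable: str, n_points: int = 200):
    grid, values = fit.response_curve(variable, n_points)
    return grid, values, float(grid[int(np.argmax(values))])


def permutation_importance(fit: MaxNet, X, y, n_repeats: int = 5, seed: int = 0) -> pd.Series:
    return fit.permutation_importance(X, y, n_repeats=n_repeats, seed=seed)
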