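import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from kelpshift.maxnet import (
    FeatureSpec,
    MaxNet,
    build_features,
    default_regularization,
    fit_maxnet,
    fit_penalized,
    penalized_objective,
)


def oracle_minimum(P, B, lam, start=None):
    """Generic direct-search minimizer of the penalized objective (the
    independent check on the production solver)."""
    n = P.shape[1]
    best = np.inf
    for x0 in ([np.zeros(n)] if start is None else [np.zeros(n), start]):
        res = minimize(
            penalized_objective, x0, args=(P, B, lam), method="Powell",
            options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 20000},
        )
        best = min(best, float(res.fun))
    return best


class TestFeatures:
    def test_linear_only_feature_count(self):
        spec = FeatureSpec(("a", "b"), ("linear",))
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert build_features(X, spec).shape == (2, 2)

    def test_lqp_feature_count_three_variables(self):
        spec = FeatureSpec(("a", "b", "c"), ("linear", "quadratic", "product"))
        X = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]})
        F = build_features(X, spec)
        assert F.shape == (1, 9)
        assert spec.feature_names == ["a", "b", "c", "a^2", "b^2", "c^2", "a*b", "a*c", "b*c"]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown feature class"):
            MaxNet(feature_classes="hinge").fit(
                pd.DataFrame({"a": np.arange(60.0)}), np.r_[np.ones(10), np.zeros(50)]
            )

    def test_prediction_inputs_clamped_to_training_range(self, rng):
        X = pd.DataFrame({"a": rng.uniform(0, 10, 110)})
        y = np.r_[np.ones(10), np.zeros(100)]
        est = MaxNet(feature_classes="l").fit(X, y)
        hi = X["a"].max()
        above = est.predict(pd.DataFrame({"a": [hi + 100.0]}))
        at_max = est.predict(pd.DataFrame({"a": [hi]}))
        assert above[0] == pytest.approx(at_max[0])


class TestFit:
    def test_identical_presence_and_background_gives_zero_coefficients(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        Xall = pd.concat([X, X], ignore_index=True)
        y = np.r_[np.ones(20), np.zeros(20)]
        est = MaxNet(feature_classes="l").fit(Xall, y)
        assert np.all(np.abs(est.coef_) < 1e-6)

    def test_presences_at_high_values_force_positive_slope(self, rng):
        bg = rng.uniform(0, 1, 200)
        pres = rng.uniform(0.8, 1.0, 20)
        est = fit_maxnet(pd.DataFrame({"a": pres}), pd.DataFrame({"a": bg}), feature_classes="l")
        assert est.coef_[0] > 0
        # oracle agreement on the same instance
        spec = est.feature_spec_
        P = build_features(pd.DataFrame({"a": pres}), spec) - est.feature_center_
        B = build_features(pd.DataFrame({"a": bg}), spec) - est.feature_center_
        ours = penalized_objective(est.coef_, P, B, np.where(np.isfinite(est.lambda_), est.lambda_, 0.0))
        assert ours <= oracle_minimum(P, B, est.lambda_, start=est.coef_) + 1e-4

    def test_huge_multiplier_kills_all_coefficients(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=120), "b": rng.normal(size=120)})
        y = np.r_[np.ones(20), np.zeros(100)]
        est = MaxNet(feature_classes="lq", beta_multiplier=1e6).fit(X, y)
        assert np.all(est.coef_ == 0)

    def test_objective_path_is_non_increasing(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
        y = np.r_[np.ones(50), np.zeros(250)]
        est = MaxNet(feature_classes="lqp").fit(X, y)
        path = np.asarray(est.objective_path_)
        assert np.all(np.diff(path) <= 1e-12)

    def test_too_few_presences_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        y = np.r_[np.ones(4), np.zeros(46)]
        with pytest.raises(ValueError, match="at least 5"):
            MaxNet().fit(X, y)

    def test_constant_feature_excluded_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=100), "b": np.ones(100)})
        y = np.r_[np.ones(10), np.zeros(90)]
        with pytest.warns(UserWarning, match="constant"):
            est = MaxNet(feature_classes="l").fit(X, y)
        assert est.coef_[list(est.feature_spec_.feature_names).index("b")] == 0


class TestPredict:
    @pytest.fixture()
    def fitted(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=220), "b": rng.normal(size=220)})
        y = np.r_[np.ones(20), np.zeros(200)]
        return MaxNet(feature_classes="lq").fit(X, y), X, y

    def test_raw_sums_to_one_over_training_background(self, fitted):
        est, X, y = fitted
        raw = est.predict(X[y == 0], output="raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_coefficients_give_uniform_raw_and_constant_cloglog(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=220)})
        y = np.r_[np.ones(20), np.zeros(200)]
        est = MaxNet(feature_classes="l", beta_multiplier=1e6).fit(X, y)
        raw = est.predict(X[y == 0], output="raw")
        np.testing.assert_allclose(raw, 1.0 / 200, rtol=1e-12)
        cll = est.predict(X, output="cloglog")
        assert np.ptp(cll) == pytest.approx(0.0, abs=1e-12)

    def test_cloglog_strictly_increasing_in_raw(self, fitted):
        est, X, _ = fitted
        raw = est.predict(X, output="raw")
        cll = est.predict(X, output="cloglog")
        order = np.argsort(raw)
        assert np.all(np.diff(cll[order]) >= 0)
        assert np.all((cll > 0) & (cll < 1))

    def test_raw_invariant_to_constant_feature_shift(self, rng):
        # with linear features a constant shift of a variable shifts its
        # feature column by a constant, which the normalizer absorbs
        X = pd.DataFrame({"a": rng.normal(size=220), "b": rng.normal(size=220)})
        y = np.r_[np.ones(20), np.zeros(200)]
        est = MaxNet(feature_classes="l").fit(X, y)
        est2 = MaxNet(feature_classes="l").fit(X + 7.5, y)
        np.testing.assert_allclose(
            est.predict(X, output="raw"), est2.predict(X + 7.5, output="raw"), rtol=1e-10
        )

    def test_feature_count_mismatch_errors(self, fitted):
        est, _, _ = fitted
        with pytest.raises((ValueError, KeyError)):
            est.predict(pd.DataFrame({"a": [1.0]}))

    def test_json_round_trip_preserves_predictions(self, fitted):
        est, X, _ = fitted
        back = MaxNet.from_json(est.to_json())
        np.testing.assert_allclose(back.predict(X), est.predict(X), rtol=0, atol=1e-12)


class TestResponseCurve:
    def _manual_fit(self, b_lin, b_quad, lo=0.0, hi=30.0):
        est = MaxNet(feature_classes="lq")
        est.variables_ = ("sst_max",)
        est.feature_spec_ = FeatureSpec(("sst_max",), ("linear", "quadratic"), ((lo, hi),))
        est.coef_ = np.array([b_lin, b_quad])
        est.lambda_ = np.zeros(2)
        est.feature_center_ = np.zeros(2)
        est.log_Z_ = 0.0
        est.Z_ = 1.0
        est.entropy_ = 1.0
        est.background_means_ = {"sst_max": 15.0}
        est.n_presence_ = est.n_background_ = 10
        est.n_features_in_ = 1
        return est

    def test_positive_linear_only_peaks_at_range_maximum(self):
        est = self._manual_fit(0.01, 0.0)
        assert est.response_peak("sst_max") == pytest.approx(30.0)

    def test_negative_quadratic_gives_interior_vertex(self):
        # exponent b1*x + b2*x^2 has its vertex at -b1/(2*b2) = 17.5;
        # coefficients small enough that cloglog does not saturate
        est = self._manual_fit(0.07, -0.002)
        grid, values = est.response_curve("sst_max", n_points=400)
        spacing = grid[1] - grid[0]
        assert abs(grid[int(np.argmax(values))] - 17.5) <= spacing

    def test_curve_length_matches_request(self):
        grid, values = self._manual_fit(0.1, -0.01).response_curve("sst_max", n_points=73)
        assert grid.size == values.size == 73

    def test_unknown_variable_errors(self):
        with pytest.raises(KeyError):
            self._manual_fit(0.1, -0.01).response_curve("salinity")


class TestPermutationImportance:
    def test_single_informative_variable_takes_all_contribution(self, rng):
        t_bg = rng.uniform(0, 10, 400)
        t_pres = rng.normal(7.0, 0.5, 60)
        noise = rng.normal(size=460)
        X = pd.DataFrame({"sst_max": np.r_[t_pres, t_bg], "turbidity": noise})
        y = np.r_[np.ones(60), np.zeros(400)]
        est = MaxNet(feature_classes="lq").fit(X, y)
        pct = est.permutation_importance(X, y, n_repeats=3, seed=0)
        assert pct["sst_max"] > 90
        assert pct["turbidity"] < 10
        assert pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_exchangeable_duplicate_variables_split_evenly(self, rng):
        t_bg = rng.uniform(0, 10, 400)
        t_pres = rng.normal(7.0, 0.5, 60)
        t = np.r_[t_pres, t_bg]
        X = pd.DataFrame({"a": t, "b": t.copy()})
        y = np.r_[np.ones(60), np.zeros(400)]
        est = MaxNet(feature_classes="l").fit(X, y)
        pct = est.permutation_importance(X, y, n_repeats=40, seed=1)
        assert pct["a"] == pytest.approx(50.0, abs=15.0)
        assert pct["b"] == pytest.approx(50.0, abs=15.0)


def test_regularization_schedule_interpolates_published_table():
    lam = default_regularization(["linear"], np.array([2.0]), m=100, multiplier=1.0)
    assert lam[0] == pytest.approx(0.05 * 2.0 / 10.0)  # r=0.05, scale 2, sqrt(100)=10
    # midway between the m=10 (r=1.0) and m=30 (r=0.2) linear breakpoints
    lam = default_regularization(["linear"], np.array([1.0]), m=20, multiplier=1.0)
    assert lam[0] == pytest.approx(0.6 / np.sqrt(20))


def test_solver_matches_oracle_on_small_instances(rng):
    for _ in range(3):
        n_feat = int(rng.integers(1, 4))
        m = int(rng.integers(5, 20))
        n = int(rng.integers(20, 50))
        P = rng.normal(size=(m, n_feat))
        B = rng.normal(size=(n, n_feat))
        lam = rng.uniform(0.01, 0.2, n_feat)
        beta, _ = fit_penalized(P, B, lam)
        ours = penalized_objective(beta, P, B, lam)
        assert abs(ours - oracle_minimum(P, B, lam, start=beta)) < 1e-4
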