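import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from divscape.grids import RasterGrid
from divscape.model import (
    DiversityModelResult,
    ModelSettings,
    bias_correct,
    cross_validate_forest,
    fit_bias_line,
    fit_tuned_forest,
    partial_dependence,
    permutation_importance,
    predict_surface,
    stratified_folds,
    uncertainty_map,
    variance_partitioning,
)


def _strong_problem(n=300, seed=5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    y = 2.0 * X["a"].to_numpy() + 0.01 * rng.normal(size=n)
    return X, y


class TestTuning:
    def test_noise_free_monotone_signal_recovered(self):
        X, y = _strong_problem()
        res = fit_tuned_forest(X, y, ModelSettings(ntree=200, seed=5, mtry_candidates=[2]))
        assert res.cv_metrics["r2"] > 0.9

    def test_pure_noise_has_near_zero_cv_r2(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 5))
        y = rng.normal(size=300)
        res = cross_validate_forest(X, y, ModelSettings(ntree=200, seed=5))
        assert abs(res["r2"]) < 0.1

    def test_single_candidate_is_chosen(self):
        X, y = _strong_problem(n=80)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=50, seed=1, mtry_candidates=[2]))
        assert res.mtry == 2
        assert len(res.cv_table) == 1

    def test_oversized_candidate_skipped_with_warning(self):
        X, y = _strong_problem(n=80)
        with pytest.warns(UserWarning, match="exceeds"):
            res = fit_tuned_forest(
                X, y, ModelSettings(ntree=50, seed=1, mtry_candidates=[2, 99])
            )
        assert list(res.cv_table["mtry"]) == [2]

    def test_chosen_mtry_attains_minimum_cv_rmse(self):
        X, y = _strong_problem(n=150)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=80, seed=2))
        table = res.cv_table.set_index("mtry")
        assert table.loc[res.mtry, "rmse"] == table["rmse"].min()
        assert len(res.best_three) == min(3, len(table))

    def test_too_few_observations_rejected(self):
        X, y = _strong_problem(n=10)
        with pytest.raises(ValueError, match="at least 20"):
            fit_tuned_forest(X, y, ModelSettings(ntree=10))

    def test_stratified_folds_cover_response_range(self):
        y = np.arange(100, dtype=float)
        folds = stratified_folds(y, 10, seed=0)
        assert sorted(np.unique(folds)) == list(range(10))
        # every fold must contain both low and high responses
        for k in range(10):
            members = y[folds == k]
            assert members.min() < 20 and members.max() > 80


class TestImportance:
    def test_sole_informative_predictor_ranks_first(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(250, 5)), columns=list("abcde"))
        y = 3.0 * X["c"].to_numpy() + 0.1 * rng.normal(size=250)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=150, seed=6, mtry_candidates=[2]))
        assert res.importance.iloc[0]["predictor"] == "c"
        assert bool(res.importance.iloc[0]["crucial"])

    def test_constant_predictor_has_near_zero_importance(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "flat"])
        X["flat"] = 1.0
        y = X["a"].to_numpy() + 0.1 * rng.normal(size=200)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=100, seed=7, mtry_candidates=[3]))
        flat = res.importance.set_index("predictor").loc["flat", "inc_mse_pct"]
        assert abs(flat) < 1e-9  # permuting a constant changes nothing

    def test_same_seed_gives_identical_table(self):
        X, y = _strong_problem(n=150)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=80, seed=3, mtry_candidates=[2]))
        again = permutation_importance(res, X, y)
        pd.testing.assert_frame_equal(res.importance, again)


class TestPartialDependence:
    def test_monotone_driver_yields_monotone_curve(self):
        X, y = _strong_problem()
        res = fit_tuned_forest(X, y, ModelSettings(ntree=200, seed=5, mtry_candidates=[3]))
        curve = partial_dependence(res, X, "a", 30)
        rho = spearmanr(curve["value"], curve["mean_prediction"]).statistic
        assert rho > 0.9

    def test_uninformative_predictor_curve_is_flat(self):
        X, y = _strong_problem(n=400)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=300, seed=5, mtry_candidates=[3]))
        curve = partial_dependence(res, X, "c", 30)
        span = curve["mean_prediction"].max() - curve["mean_prediction"].min()
        assert span < 0.1 * y.std()

    def test_single_grid_point_equals_mean_training_prediction(self):
        X, y = _strong_problem(n=100)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=50, seed=4, mtry_candidates=[2]))
        curve = partial_dependence(res, X, "b", 1)
        assert len(curve) == 1
        Xmid = X.to_numpy().copy()
        j = res.feature_names.index("b")
        Xmid[:, j] = (X["b"].min() + X["b"].max()) / 2
        assert curve["mean_prediction"].iloc[0] == pytest.approx(
            res.forest.predict(Xmid).mean()
        )

    def test_unknown_predictor_rejected(self):
        X, y = _strong_problem(n=80)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=30, seed=1, mtry_candidates=[2]))
        with pytest.raises(ValueError, match="zzz"):
            partial_dependence(res, X, "zzz")


class TestVariancePartitioning:
    def test_single_group_fraction_equals_full_model_r2(self):
        X, y = _strong_problem(n=150)
        labels = dict.fromkeys(X.columns, "climate")
        vp = variance_partitioning(X, labels, y, ModelSettings(ntree=80, seed=1))
        assert list(vp.components) == [frozenset({"climate"})]
        assert vp.components[frozenset({"climate"})] == pytest.approx(vp.full_r2)

    def test_lattice_components_sum_to_full_r2(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=["clim01", "clim02", "soil01", "soil02", "slope", "ad"])
        y = X["clim01"].to_numpy() + 0.5 * X["soil01"].to_numpy() + 0.2 * rng.normal(size=200)
        labels = {c: g for c, g in zip(X.columns,
                  ["climate", "climate", "soil", "soil", "topography", "anthropogenic"])}
        vp = variance_partitioning(X, labels, y, ModelSettings(ntree=60, seed=8))
        assert len(vp.components) == 15
        assert sum(vp.components.values()) == pytest.approx(vp.full_r2, abs=1e-9)
        assert vp.residual == pytest.approx(1 - vp.full_r2)

    def test_single_group_driver_takes_largest_unique_fraction(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(250, 4)),
                         columns=["clim01", "clim02", "soil01", "soil02"])
        y = 2.0 * X["clim01"].to_numpy() + 0.1 * rng.normal(size=250)
        labels = {"clim01": "climate", "clim02": "climate",
                  "soil01": "soil", "soil02": "soil"}
        vp = variance_partitioning(X, labels, y, ModelSettings(ntree=100, seed=9))
        top = max(vp.components, key=vp.components.get)
        assert top == frozenset({"climate"})

    def test_duplicated_driver_across_groups_is_shared(self):
        rng = np.random.default_rng(10)
        driver = rng.normal(size=250)
        X = pd.DataFrame({
            "clim01": driver + 0.01 * rng.normal(size=250),
            "soil01": driver + 0.01 * rng.normal(size=250),
        })
        y = driver + 0.1 * rng.normal(size=250)
        labels = {"clim01": "climate", "soil01": "soil"}
        vp = variance_partitioning(X, labels, y, ModelSettings(ntree=100, seed=10))
        shared = vp.components[frozenset({"climate", "soil"})]
        assert shared > vp.components[frozenset({"climate"})]
        assert shared > vp.components[frozenset({"soil"})]

    def test_display_rule_hides_small_fractions(self):
        X, y = _strong_problem(n=150)
        labels = dict.fromkeys(X.columns, "climate")
        vp = variance_partitioning(X, labels, y, ModelSettings(ntree=60, seed=2))
        view = vp.report(min_fraction=0.01)
        assert (view["fraction"] > 0.01).all()


def _fake_result(y, preds, a=1.0, b=0.0):
    return DiversityModelResult(
        forest=None, feature_names=["x"], mtry=1,
        cv_table=pd.DataFrame({"mtry": [1], "r2": [0], "mae": [0], "rmse": [0]}),
        best_three=pd.DataFrame(), cv_predictions=np.asarray(preds, float),
        y=np.asarray(y, float), bias_a=a, bias_b=b, settings=ModelSettings(ntree=1),
    )


class TestBiasCorrection:
    def _surface(self, values):
        return RasterGrid(np.asarray(values, dtype=float), 0, 0, 20.0)

    def test_identity_calibration_leaves_surface_unchanged(self):
        res = _fake_result([1, 2], [1, 2], a=1.0, b=0.0)
        s = self._surface([[3.0, 7.0]])
        np.testing.assert_allclose(bias_correct(res, s).values, s.values)

    def test_hand_computed_inversion(self):
        res = _fake_result([1, 2], [1, 2], a=0.5, b=2.0)
        out = bias_correct(res, self._surface([[7.0]]))
        assert out.values[0, 0] == pytest.approx(10.0)  # (7 - 2) / 0.5

    def test_negative_corrections_clamp_to_zero_not_nodata(self):
        res = _fake_result([1, 2], [1, 2], a=1.0, b=5.0)
        out = bias_correct(res, self._surface([[3.0, np.nan]]))
        assert out.values[0, 0] == 0.0
        assert np.isnan(out.values[0, 1])

    def test_degenerate_slope_rejected(self):
        res = _fake_result([1, 2], [1, 2], a=0.0, b=0.0)
        with pytest.raises(ValueError, match="slope"):
            bias_correct(res, self._surface([[1.0]]))

    def test_round_trip_restores_unit_line(self):
        # correcting the very predictions the line was fitted on must give
        # values regressing on the observations with slope 1, intercept 0
        rng = np.random.default_rng(11)
        obs = rng.uniform(5, 50, size=200)
        pred = 0.6 * obs + 8 + rng.normal(0, 1.5, size=200)
        a, b = fit_bias_line(obs, pred)
        corrected = (pred - b) / a
        assert corrected.min() > 0  # no clamping occurs
        slope, intercept = np.polyfit(obs, corrected, 1)
        assert slope == pytest.approx(1.0, abs=1e-6)
        assert intercept == pytest.approx(0.0, abs=1e-6)


class TestPredictSurface:
    def _fitted(self):
        X, y = _strong_problem(n=100)
        res = fit_tuned_forest(X, y, ModelSettings(ntree=50, seed=3, mtry_candidates=[2]))
        return X, res

    def test_constant_stack_matches_single_row_prediction(self):
        X, res = self._fitted()
        row = X.iloc[10]
        stack = {
            name: RasterGrid(np.full((4, 5), row[name]), 0, 0, 20.0)
            for name in res.feature_names
        }
        out = predict_surface(res, stack)
        expected = res.forest.predict(row.to_frame().T.to_numpy())[0]
        np.testing.assert_allclose(out.values, expected)

    def test_nodata_in_any_layer_propagates(self):
        X, res = self._fitted()
        stack = {
            name: RasterGrid(np.full((3, 3), X[name].mean()), 0, 0, 20.0)
            for name in res.feature_names
        }
        vals = stack["b"].values.copy()
        vals[1, 1] = np.nan
        stack["b"] = stack["b"].copy_with(vals)
        out = predict_surface(res, stack)
        assert np.isnan(out.values[1, 1])
        assert np.isfinite(np.delete(out.values.ravel(), 4)).all()

    def test_missing_layer_named_in_error(self):
        X, res = self._fitted()
        stack = {"a": RasterGrid(np.zeros((2, 2)), 0, 0, 20.0)}
        with pytest.raises(ValueError, match="'b'"):
            predict_surface(res, stack)


class TestUncertaintyMap:
    def _template(self, n=30):
        return RasterGrid(np.zeros((n, n)), 0, 0, 20.0)

    def _plots(self, coords):
        return pd.DataFrame(coords, columns=["x", "y"])

    def test_equal_residuals_collapse_to_strongly_predictive(self):
        res = _fake_result([5, 5, 5, 5], [4, 4, 4, 4])
        plots = self._plots([(100, 100), (300, 300), (500, 100), (200, 400)])
        umap = uncertainty_map(res, plots, self._template())
        assert np.all(umap.classes.values == 1.0)
        assert umap.levels[0] == "Strongly predictive"

    def test_outlier_plot_neighbourhood_is_less_predictive(self):
        res = _fake_result([5, 5, 5, 5, 30], [5.1, 4.9, 5.05, 4.95, 5.0])
        plots = self._plots([(100, 500), (500, 500), (100, 100), (300, 300), (520, 80)])
        umap = uncertainty_map(res, plots, self._template())
        row, col = umap.classes.index_of(520, 80)
        assert umap.classes.values[row, col] == 3.0  # worst tercile

    def test_terciles_split_valid_cells_evenly(self):
        rng = np.random.default_rng(12)
        res = _fake_result(rng.uniform(0, 10, 12), rng.uniform(0, 10, 12))
        plots = self._plots(rng.uniform(0, 600, size=(12, 2)))
        umap = uncertainty_map(res, plots, self._template())
        counts = pd.Series(umap.classes.values.ravel()).value_counts(normalize=True)
        for level in (1.0, 2.0, 3.0):
            assert counts[level] == pytest.approx(1 / 3, abs=0.02)

    def test_fewer_than_three_plots_rejected(self):
        res = _fake_result([1, 2], [1, 2])
        with pytest.raises(ValueError, match="3 plots"):
            uncertainty_map(res, self._plots([(0, 0), (10, 10)]), self._template())
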