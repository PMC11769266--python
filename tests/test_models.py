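"""Split, fits, metrics, VIF screening, selection loop and comparison stats."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from statsmodels.stats.outliers_influence import variance_inflation_factor as sm_vif

from canopy_yield.models import (
    FeatureTable,
    InsufficientDataError,
    LinearYieldRegressor,
    ModelConfig,
    NegativeIntervalError,
    VIFImportanceSelector,
    collinearity_screen,
    compare_methods,
    days_after_planting,
    evaluate,
    fit_model,
    iterative_feature_selection,
    soil_inclusion_test,
    split_train_test,
    variance_inflation_factors,
)


def table(X: dict, y, **kw) -> FeatureTable:
    df = pd.DataFrame(X)
    df["yield_mg_ha"] = y
    return FeatureTable(data=df, **kw)


class TestSplit:
    @pytest.mark.parametrize("n, ratio, n_train", [(8581, 0.8, 6865), (10, 0.8, 8), (5, 0.5, 3)])
    def test_split_sizes(self, n, ratio, n_train, rng):
        t = table({"x": rng.random(n)}, rng.random(n))
        train, test = split_train_test(t, ratio, seed=0)
        assert (train.n, test.n) == (n_train, n - n_train)

    def test_disjoint_exhaustive_reproducible(self, rng):
        t = table({"x": rng.random(100)}, rng.random(100))
        a_train, a_test = split_train_test(t, 0.8, seed=5)
        b_train, b_test = split_train_test(t, 0.8, seed=5)
        assert list(a_train.data.index) == list(b_train.data.index)
        combined = set(a_train.data.index) | set(a_test.data.index)
        assert combined == set(t.data.index)
        assert not (set(a_train.data.index) & set(a_test.data.index))
        c_train, _ = split_train_test(t, 0.8, seed=6)
        assert list(c_train.data.index) != list(a_train.data.index)

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            split_train_test(table({"x": [1.0]}, [1.0]), 0.8, 0)


class TestFits:
    def test_mlr_exact_line(self):
        x = np.arange(10.0)
        t = table({"x": x}, 2.0 * x + 1.0)
        fit = fit_model(ModelConfig("MLR"), t)
        assert fit.estimator.intercept_ == pytest.approx(1.0, abs=1e-9)
        assert fit.estimator.coef_[0] == pytest.approx(2.0, abs=1e-9)
        m = evaluate(fit, t)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_mlr_rank_deficiency_warns_and_still_predicts(self, rng):
        x = rng.random(30)
        t = table({"a": x, "b": x}, 3.0 * x)  # duplicated column
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit = fit_model(ModelConfig("MLR"), t)
        assert evaluate(fit, t).rmse == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("kind", ["RF", "GBR", "XGB"])
    def test_ensemble_constant_target(self, kind, rng):
        t = table({"x": rng.random(40), "z": rng.random(40)}, np.full(40, 5.0))
        fit = fit_model(ModelConfig(kind, seed=0), t)
        np.testing.assert_allclose(fit.predict(t.X), 5.0, atol=1e-6)

    @pytest.mark.parametrize("kind", ["RF", "GBR", "XGB"])
    def test_seeded_determinism(self, kind, rng):
        X = {"a": rng.random(60), "b": rng.random(60)}
        y = rng.random(60)
        t = table(X, y)
        p1 = fit_model(ModelConfig(kind, seed=3), t).predict(t.X)
        p2 = fit_model(ModelConfig(kind, seed=3), t).predict(t.X)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("kind", ["RF", "GBR", "XGB"])
    def test_importances_sum_to_one(self, kind, rng):
        t = table({"a": rng.random(60), "b": rng.random(60)}, rng.random(60))
        fit = fit_model(ModelConfig(kind, seed=0), t)
        assert (fit.feature_importances >= 0).all()
        assert fit.feature_importances.sum() == pytest.approx(1.0, rel=1e-6)

    def test_default_hyperparameters_applied(self):
        est = ModelConfig("RF").resolved_hyperparameters()
        assert est == {"max_depth": 21, "max_features": 11, "n_estimators": 500}
        assert ModelConfig("XGB").resolved_hyperparameters()["gamma"] == pytest.approx(0.30)


class TestMetrics:
    def test_perfect_prediction(self):
        t = table({"x": [1.0, 2.0, 3.0]}, [2.0, 4.0, 6.0])
        fit = fit_model(ModelConfig("MLR"), t)
        m = evaluate(fit, t)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_rmse_closed_form(self):
        obs = np.array([10.0, 12.0, 14.0])
        pred = np.array([11.0, 11.0, 15.0])
        rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
        assert rmse == pytest.approx(1.0)

        class Stub:
            feature_names = ["x"]

            def predict(self, X):
                return pred

        from canopy_yield.models import FitResult

        fr = FitResult(ModelConfig("MLR"), Stub(), ["x"], pd.Series([1.0], index=["x"]), [])
        fr.predict = lambda X: pred
        m = evaluate(fr, table({"x": [0.0, 0.0, 0.0]}, obs))
        assert m.rmse == pytest.approx(1.0)

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        from canopy_yield.models import FitResult

        fr = FitResult(ModelConfig("MLR"), None, ["x"], pd.Series([1.0], index=["x"]), [])
        fr.predict = lambda X: np.full(4, obs.mean())
        m = evaluate(fr, table({"x": np.zeros(4)}, obs))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_target_r2_undefined(self):
        from canopy_yield.models import FitResult

        fr = FitResult(ModelConfig("MLR"), None, ["x"], pd.Series([1.0], index=["x"]), [])
        fr.predict = lambda X: np.array([1.0, 2.0])
        m = evaluate(fr, table({"x": [0.0, 0.0]}, [5.0, 5.0]))
        assert np.isnan(m.r2)
        assert m.rmse > 0


class TestVIF:
    def test_orthogonal_predictors_vif_one(self):
        n = 64
        t_arr = np.arange(n)
        a = np.where(t_arr % 2 == 0, 1.0, -1.0)
        b = np.where((t_arr // 2) % 2 == 0, 1.0, -1.0)
        vifs = variance_inflation_factors(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(vifs, 1.0, atol=1e-9)
        assert collinearity_screen(table({"a": a, "b": b}, np.ones(n)), 10.0) == []

    def test_duplicated_column_infinite_vif(self, rng):
        x = rng.random(50)
        vifs = variance_inflation_factors(pd.DataFrame({"a": x, "b": x, "c": rng.random(50)}))
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])
        flagged = collinearity_screen(table({"a": x, "b": x, "c": rng.random(50)}, x), 10.0)
        assert flagged[:2] == ["a", "b"]  # infinite first, alphabetical tie-break

    def test_matches_statsmodels_oracle(self, rng):
        z = rng.standard_normal(200)
        X = pd.DataFrame(
            {
                "a": z + 0.4 * rng.standard_normal(200),
                "b": z + 0.4 * rng.standard_normal(200),
                "c": rng.standard_normal(200),
            }
        )
        ours = variance_inflation_factors(X)
        exog = np.column_stack([np.ones(len(X)), X.to_numpy()])
        for j, name in enumerate(X.columns):
            assert ours[name] == pytest.approx(sm_vif(exog, j + 1), rel=1e-9)


class TestSelection:
    def _informative_table(self, rng, n=1000):
        x = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        y = 3.0 * x + 1.0 * rng.standard_normal(n)
        return table({"signal": x, "noise": noise}, y)

    def test_noise_predictor_eliminated(self, rng):
        t = self._informative_table(rng)
        train, test = split_train_test(t, 0.8, 0)
        selected, history = iterative_feature_selection(
            train, test, ModelConfig("MLR", seed=0), importance_floor=0.05
        )
        assert selected == ["signal"]
        assert len(history) >= 2

    def test_identity_when_nothing_droppable(self, rng):
        x = rng.standard_normal(200)
        z = rng.standard_normal(200)
        t = table({"a": x, "b": z}, x + z)
        train, test = split_train_test(t, 0.8, 0)
        selected, history = iterative_feature_selection(
            train, test, ModelConfig("MLR", seed=0), importance_floor=0.001
        )
        assert len(history) == 1
        assert set(selected) == {"a", "b"}

    def test_duplicated_informative_column_one_copy_survives(self, rng):
        x = rng.standard_normal(300)
        t = table({"a": x, "b": x}, 2.0 * x + 0.05 * rng.standard_normal(300))
        train, test = split_train_test(t, 0.8, 0)
        with pytest.warns(UserWarning, match="rank-deficient"):
            selected, _ = iterative_feature_selection(
                train, test, ModelConfig("MLR", seed=0), importance_floor=0.001
            )
        assert len(selected) == 1

    def test_sklearn_selector_wrapper(self, rng):
        t = self._informative_table(rng)
        sel = VIFImportanceSelector(kind="MLR", importance_floor=0.05, seed=0)
        sel.fit(t.X, t.y)
        assert sel.selected_features_ == ["signal"]
        out = sel.transform(t.X)
        assert list(out.columns) == ["signal"]


class TestCompareMethods:
    def test_identical_vectors_all_same_letter(self):
        p, letters = compare_methods({"A": [1.0, 1.0, 1.0], "B": [1.0, 1.0, 1.0]})
        assert p == 1.0
        assert set(letters.values()) == {"a"}

    def test_well_separated_groups_distinct_letters(self, rng):
        a = 1.0 + 0.01 * rng.standard_normal(7)
        b = 2.0 + 0.01 * rng.standard_normal(7)
        p, letters = compare_methods({"low": a, "high": b})
        assert p < 1e-6
        assert letters["high"] == "a" and letters["low"] == "b"

    def test_textbook_hand_computation(self):
        """Three methods, four stage-replicates each.
        Means: X 2.0, Y 1.5, Z 1.45; every group has SS = 0.02, so
        MSE = 0.06/9, LSD = t(.975, 9) * sqrt(2*MSE/4) = 2.2622*0.05774 = 0.1306.
        |X-Y| = 0.5 and |X-Z| = 0.55 exceed the LSD, |Y-Z| = 0.05 does not:
        X alone gets 'a'; Y and Z share 'b'."""
        data = {
            "X": [2.0, 2.1, 1.9, 2.0],
            "Y": [1.5, 1.6, 1.4, 1.5],
            "Z": [1.45, 1.35, 1.55, 1.45],
        }
        p, letters = compare_methods(data)
        assert p < 0.001
        assert letters == {"X": "a", "Y": "b", "Z": "b"}

    def test_overlapping_middle_group_shares_letters(self):
        data = {
            "X": [2.0, 2.1, 1.9, 2.0],
            "Y": [1.93, 2.0, 1.86, 1.93],   # within LSD of X, beyond Z
            "Z": [1.70, 1.77, 1.63, 1.70],
        }
        p, letters = compare_methods(data)
        assert p < 0.05
        assert letters["X"] == "a"
        assert letters["Z"] != letters["X"]
        assert set(letters["Y"]) & set(letters["X"])  # Y shares a letter with X

    def test_every_method_shares_a_letter_with_itself(self, rng):
        vals = {m: rng.random(5).tolist() for m in "ABCD"}
        _, letters = compare_methods(vals)
        assert all(letters[m] for m in vals)

    def test_unequal_replicates_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_methods({"A": [1.0, 2.0], "B": [1.0]})


class TestSoilInclusion:
    def test_identical_lists_boundary_half(self):
        assert soil_inclusion_test([1.0, 1.1, 0.9], [1.0, 1.1, 0.9]) == 0.5

    def test_constant_shift_rejects(self, rng):
        full = 1.0 + 0.001 * rng.standard_normal(10)
        assert soil_inclusion_test(full, full + 1.0) < 0.001

    def test_matches_independent_t_cdf(self, rng):
        full = rng.random(12)
        red = full + rng.standard_normal(12) * 0.3
        p = soil_inclusion_test(full, red)
        d = red - full
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        # independent evaluation through the regularized incomplete beta CDF
        p_oracle = float(special.stdtr(len(d) - 1, -t_stat))
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_wrong_direction_gives_large_p(self, rng):
        full = 2.0 + 0.001 * rng.standard_normal(10)
        assert soil_inclusion_test(full, full - 1.0) > 0.999


class TestDaysAfterPlanting:
    @pytest.mark.parametrize(
        "flight, dap",
        [
            (dt.date(2023, 3, 20), 20),
            (dt.date(2023, 5, 22), 83),
            (dt.date(2023, 8, 14), 167),
            (dt.date(2023, 2, 28), 0),
        ],
    )
    def test_calendar_difference(self, flight, dap):
        assert days_after_planting(dt.date(2023, 2, 28), flight) == dap

    def test_negative_interval_rejected(self):
        with pytest.raises(NegativeIntervalError):
            days_after_planting(dt.date(2023, 2, 28), dt.date(2023, 1, 1))
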