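import numpy as np
import pandas as pd
import pytest

from wheatda.rasters import Raster
from wheatda.yield_mapping import (
    LAI_STAGE_WEIGHTS,
    SM_STAGE_WEIGHTS,
    StageWeights,
    StageWeightedYieldModel,
    compare_strategies,
    fit_yield_model,
    predict_yield,
    stage_composite,
    validate,
)


class TestStageWeights:
    def test_default_weight_sets_sum_to_one(self):
        assert LAI_STAGE_WEIGHTS.as_array().sum() == pytest.approx(1.0, abs=1e-6)
        assert SM_STAGE_WEIGHTS.as_array().sum() == pytest.approx(1.0, abs=1e-6)

    def test_non_normalised_weights_rejected(self):
        with pytest.raises(ValueError):
            StageWeights("LAI", (0.3, 0.3, 0.3, 0.3))
        with pytest.raises(ValueError):
            StageWeights("LAI", (-0.1, 0.5, 0.4, 0.2))


class TestStageComposite:
    def test_constant_profile_returns_the_constant(self):
        assert stage_composite((3.3, 3.3, 3.3, 3.3), LAI_STAGE_WEIGHTS) == pytest.approx(3.3)

    def test_unit_vector_reads_single_weight(self):
        assert stage_composite((0, 0, 1, 0), LAI_STAGE_WEIGHTS) == pytest.approx(0.5660)

    def test_hand_dot_product(self):
        assert stage_composite((1, 2, 4, 3), LAI_STAGE_WEIGHTS) == pytest.approx(3.191)

    def test_linearity(self):
        v = np.array([1.0, 2, 4, 3])
        assert stage_composite(3 * v, LAI_STAGE_WEIGHTS) == pytest.approx(
            3 * stage_composite(v, LAI_STAGE_WEIGHTS)
        )

    def test_missing_stage_named_in_error(self):
        with pytest.raises(ValueError, match="jointing"):
            stage_composite({"green_up": 1, "heading_filling": 2, "milking": 1},
                            LAI_STAGE_WEIGHTS)


def _ols_oracle(X, y):
    X1 = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(X1.T @ X1, X1.T @ y)


class TestYieldModelFit:
    def test_recovers_known_single_predictor_model(self):
        """Sites generated exactly from Y = 1041.9*LAI + 1031.4 fit back exactly."""
        lai = np.linspace(2.0, 6.0, 10)
        y = 1041.9 * lai + 1031.4
        res = fit_yield_model(
            pd.DataFrame({"lai_composite": lai}), y, "irrigated", "LAI_only"
        )
        assert res.coefficients["lai_composite"] == pytest.approx(1041.9, abs=1e-6)
        assert res.intercept == pytest.approx(1031.4, abs=1e-6)
        assert res.r2 == pytest.approx(1.0)

    def test_two_predictor_fit_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        X = rng.uniform([2, 0.15], [6, 0.35], size=(12, 2))
        y = 900.0 * X[:, 0] + 5000.0 * X[:, 1] + 700 + rng.normal(0, 50, 12)
        df = pd.DataFrame(X, columns=["lai_composite", "sm_composite"])
        res = fit_yield_model(df, y, "rain_fed", "joint")
        b = _ols_oracle(X, y)
        assert res.intercept == pytest.approx(b[0], abs=1e-9)
        assert res.coefficients["lai_composite"] == pytest.approx(b[1], abs=1e-9)
        assert res.coefficients["sm_composite"] == pytest.approx(b[2], abs=1e-9)
        # fitted values on the training sites reproduce the OLS projection
        np.testing.assert_allclose(
            res.predict(df), np.column_stack([np.ones(12), X]) @ b, atol=1e-9
        )

    def test_collinear_joint_predictors_rejected(self):
        lai = np.linspace(2, 6, 8)
        df = pd.DataFrame({"lai_composite": lai, "sm_composite": 2 * lai})
        with pytest.raises(ValueError, match="collinear"):
            fit_yield_model(df, 1000 * lai, "rain_fed", "joint")

    def test_too_few_sites_rejected(self):
        df = pd.DataFrame({"lai_composite": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_yield_model(df, [1000.0, 2000.0], "irrigated", "LAI_only")

    def test_significance_classes(self):
        rng = np.random.default_rng(1)
        lai = np.linspace(2, 6, 30)
        strong = fit_yield_model(
            pd.DataFrame({"lai_composite": lai}),
            1000 * lai + rng.normal(0, 10, 30),
            "irrigated",
            "LAI_only",
        )
        assert strong.p_class == "***"
        noise = fit_yield_model(
            pd.DataFrame({"lai_composite": lai}),
            5000 + rng.normal(0, 500, 30),
            "irrigated",
            "LAI_only",
        )
        assert noise.p_class in ("ns", "*")


class TestPredictYield:
    @pytest.fixture()
    def irrigated_model(self):
        lai = np.linspace(2.0, 6.0, 10)
        return fit_yield_model(
            pd.DataFrame({"lai_composite": lai}),
            1041.9 * lai + 1031.4,
            "irrigated",
            "LAI_only",
        )

    def test_known_coefficient_readouts(self, irrigated_model):
        codes = Raster(np.ones((2, 2)))
        three = Raster(np.full((2, 2), 3.0))
        out = predict_yield({"irrigated": irrigated_model}, codes, lai_composite=three)
        np.testing.assert_allclose(out.data, 4157.1, atol=1e-6)
        zeros = Raster(np.zeros((2, 2)))
        out0 = predict_yield({"irrigated": irrigated_model}, codes, lai_composite=zeros)
        np.testing.assert_allclose(out0.data, 1031.4, atol=1e-6)

    def test_pixels_outside_regimes_are_nodata(self, irrigated_model):
        codes = Raster(np.array([[0.0, 1.0], [np.nan, 2.0]]))
        comp = Raster(np.full((2, 2), 3.0))
        out = predict_yield({"irrigated": irrigated_model}, codes, lai_composite=comp)
        assert np.isnan(out.data[0, 0]) and np.isnan(out.data[1, 0])
        assert np.isnan(out.data[1, 1])  # no rain-fed model supplied
        assert out.data[0, 1] == pytest.approx(4157.1, abs=1e-6)

    def test_missing_regime_mask_rejected(self, irrigated_model):
        with pytest.raises(ValueError, match="mask"):
            predict_yield({"irrigated": irrigated_model}, None,
                          lai_composite=Raster(np.ones((2, 2))))


class TestValidation:
    def test_perfect_prediction(self):
        rep = validate([1000.0, 2000.0], [1000.0, 2000.0])
        assert rep.rmse == pytest.approx(0.0)
        assert rep.are == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        rep = validate([1100.0, 900.0], [1000.0, 1000.0])
        assert rep.rmse == pytest.approx(100.0)
        assert rep.are == pytest.approx(10.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            validate([1000.0], [900.0])
        with pytest.raises(ValueError):
            validate([1000.0, 1000.0], [0.0, 1000.0])


class TestCompareStrategies:
    def _report(self, regime, strategy, rmse, are):
        rep = validate([1000.0 + rmse, 1000.0 - rmse], [1000.0, 1000.0], regime, strategy)
        assert rep.rmse == pytest.approx(rmse)
        return rep

    def test_published_style_metrics_rank_expected_winners(self):
        reports = [
            self._report("irrigated", "LAI_only", 427.57, 6.07),
            self._report("irrigated", "SM_only", 533.64, 8.49),
            self._report("irrigated", "joint", 436.71, 6.16),
            self._report("rain_fed", "LAI_only", 612.93, 12.47),
            self._report("rain_fed", "SM_only", 467.37, 11.44),
            self._report("rain_fed", "joint", 424.75, 9.55),
        ]
        table = compare_strategies(reports)
        winners = {
            r.regime: r.strategy for r in table[table.recommended].itertuples(index=False)
        }
        assert winners == {"irrigated": "LAI_only", "rain_fed": "joint"}

    def test_tie_breaks_by_declaration_order_and_flags(self):
        reports = [
            self._report("irrigated", "SM_only", 400.0, 5.0),
            self._report("irrigated", "LAI_only", 400.0, 5.0),
        ]
        with pytest.warns(UserWarning, match="tie"):
            table = compare_strategies(reports)
        assert table[table.recommended].strategy.iloc[0] == "LAI_only"
        assert table.tie.all()

    def test_single_strategy_wins_with_warning(self):
        with pytest.warns(UserWarning, match="single"):
            table = compare_strategies([self._report("rain_fed", "joint", 300.0, 4.0)])
        assert table.recommended.iloc[0]
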