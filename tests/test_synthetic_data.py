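import datetime as dt
from dataclasses import replace

import numpy as np
import pytest

from wheatda import retrieval as rt
from wheatda.area_classification import regime_split
from wheatda.crop_model import Stage
from wheatda.synthetic_data import (
    Scenario,
    ScenarioConfig,
    generate_truth,
    generate_weather,
)

SMALL = ScenarioConfig(
    seed=0, n_irrigated=6, n_rainfed=5, grid_shape=(28, 24), background_rows=4,
    n_cal_irrigated=3, n_cal_rainfed=3,
)
NOISE_FREE = replace(
    SMALL, reflectance_sd=0.0, backscatter_sd_db=0.0,
    meas_sd_lai=0.0, meas_sd_sm=0.0, meas_sd_yield=0.0,
)


@pytest.fixture(scope="module")
def scenario():
    return Scenario(SMALL)


@pytest.fixture(scope="module")
def clean_scenario():
    return Scenario(NOISE_FREE)


class TestWeather:
    def test_deterministic_under_seed(self):
        a = generate_weather(SMALL)
        b = generate_weather(SMALL)
        assert [(w.date, w.tmax, w.precip) for w in a] == [
            (w.date, w.tmax, w.precip) for w in b
        ]

    def test_zero_event_rate_means_dry_season(self):
        wx = generate_weather(replace(SMALL, precip_event_rate=0.0))
        assert sum(w.precip for w in wx) == 0.0

    def test_mean_seasonal_total_near_configured_target(self):
        totals = [
            sum(w.precip for w in generate_weather(replace(SMALL, seed=s)))
            for s in range(10)
        ]
        n_days = (SMALL.season_end - SMALL.season_start).days + 1
        target = SMALL.precip_event_rate * n_days * SMALL.precip_mean_depth
        assert abs(np.mean(totals) - target) / target < 0.2


class TestTruth:
    def test_all_irrigated_when_mix_is_pure(self):
        sc = Scenario(replace(SMALL, n_rainfed=0, n_cal_rainfed=0))
        assert all(t.regime == "irrigated" for t in sc.truths)

    def test_rainfed_sees_stress_and_irrigated_does_not(self, scenario):
        for t in scenario.truths:
            df = t.trajectory.to_dataframe()
            season = df[df.date >= t.trajectory.stage_start(Stage.GREEN_UP)]
            if t.regime == "irrigated":
                assert season.stress.min() >= 0.8
            else:
                assert season.stress.min() < 1.0

    def test_rainfed_yields_lower_than_irrigated(self, scenario):
        med = {
            reg: np.median(
                [t.trajectory.yield_ for t in scenario.truths if t.regime == reg]
            )
            for reg in ("irrigated", "rain_fed")
        }
        assert med["rain_fed"] < med["irrigated"]

    def test_terrain_reproduces_configured_regime_mix(self, scenario):
        wheat = scenario.field_ids.like((scenario.field_ids.data >= 0).astype(float))
        mask = regime_split(wheat, scenario.terrain)
        truth = scenario.regime_truth_mask()
        agree = mask.codes.data == truth.codes.data
        assert agree.mean() > 0.99

    def test_determinism_under_config_seed(self):
        a = Scenario(SMALL)
        b = Scenario(SMALL)
        assert [t.trajectory.yield_ for t in a.truths] == [
            t.trajectory.yield_ for t in b.truths
        ]


class TestRendering:
    def test_zero_noise_optical_round_trip(self, clean_scenario):
        date = dt.date(2019, 4, 16)
        scene = clean_scenario.render_optical(date)
        lai = rt.apply_retrieval(
            rt.lai_model_from_coefficients(), rt.ndvi(scene.red.data, scene.nir.data)
        )
        truth = clean_scenario.truth_raster(date, "lai").data
        np.testing.assert_allclose(lai, truth, atol=1e-6)

    def test_zero_noise_sar_round_trip(self, clean_scenario):
        date = dt.date(2019, 4, 19)
        sar = clean_scenario.render_sar(date)
        optical = clean_scenario.render_optical(date)
        m_veg = rt.mveg_from_ndwi(rt.ndwi(optical.nir.data, optical.mir.data))
        sigma_soil = rt.wcm_invert(
            rt.db_to_linear(sar.sigma_can_db.data), m_veg, sar.incidence_deg
        )
        sm = rt.apply_retrieval(
            rt.sm_model_from_coefficients(), rt.linear_to_db(sigma_soil)
        )
        truth = clean_scenario.truth_raster(date, "sm").data
        np.testing.assert_allclose(sm, truth, atol=1e-6)

    def test_wetter_soil_means_stronger_soil_backscatter(self, clean_scenario):
        """The rendering chain is monotone: ranking of pixel moisture is
        preserved in the noise-free inverted soil backscatter."""
        date = dt.date(2019, 4, 19)
        sar = clean_scenario.render_sar(date)
        optical = clean_scenario.render_optical(date)
        m_veg = rt.mveg_from_ndwi(rt.ndwi(optical.nir.data, optical.mir.data))
        sigma_soil = rt.wcm_invert(
            rt.db_to_linear(sar.sigma_can_db.data), m_veg, sar.incidence_deg
        )
        theta = clean_scenario.truth_raster(date, "sm").data
        flat_t, flat_s = theta.ravel(), sigma_soil.ravel()
        order = np.argsort(flat_t)
        assert np.all(np.diff(flat_s[order]) >= -1e-12)

    def test_cloud_masked_date_is_all_nodata(self):
        sc = Scenario(replace(SMALL, cloud_masked_dates=(dt.date(2019, 4, 16),)))
        scene = sc.render_optical(dt.date(2019, 4, 16))
        assert np.all(np.isnan(scene.red.data))

    def test_scene_level_retrieval_errors_near_configured_targets(self):
        """Default sensor noise yields retrieval RMSEs near the design targets
        (LAI ~1 m2 m-2, soil moisture ~0.03 cm3 cm-3) across seeds."""
        lai_rmse, sm_rmse = [], []
        for seed in range(12):
            sc = Scenario(replace(SMALL, seed=seed))
            rng = np.random.default_rng(500 + seed)
            w = sc.field_ids.data >= 0
            d1 = dt.date(2019, 4, 16)
            scene = sc.render_optical(d1, rng)
            lai = rt.apply_retrieval(
                rt.lai_model_from_coefficients(), rt.ndvi(scene.red.data, scene.nir.data)
            )
            lai_rmse.append(
                np.sqrt(np.mean((lai[w] - sc.truth_raster(d1, "lai").data[w]) ** 2))
            )
            d2 = dt.date(2019, 4, 19)
            sar = sc.render_sar(d2, rng)
            optical = sc.render_optical(d2, rng)
            m_veg = rt.mveg_from_ndwi(rt.ndwi(optical.nir.data, optical.mir.data))
            sigma = rt.wcm_invert(
                rt.db_to_linear(sar.sigma_can_db.data), m_veg, sar.incidence_deg
            )
            with np.errstate(invalid="ignore"):
                sm = rt.apply_retrieval(
                    rt.sm_model_from_coefficients(),
                    10 * np.log10(np.where(sigma > 0, sigma, np.nan)),
                )
            sm_rmse.append(
                np.sqrt(np.nanmean((sm[w] - sc.truth_raster(d2, "sm").data[w]) ** 2))
            )
        assert abs(np.mean(lai_rmse) - 1.0) / 1.0 < 0.3
        assert abs(np.mean(sm_rmse) - 0.03) / 0.03 < 0.3


class TestFieldSamples:
    def test_noise_free_samples_equal_truth(self, clean_scenario):
        df = clean_scenario.sample_field_measurements()
        for _, row in df.iterrows():
            t = next(x for x in clean_scenario.truths if x.site_id == row["site_id"])
            assert row["yield"] == pytest.approx(t.trajectory.yield_)
            assert row["lai_1"] == pytest.approx(
                t.value_at(dt.date(2019, 3, 17), "lai"), abs=1e-9
            )
            assert row["sm_2"] == pytest.approx(
                t.value_at(dt.date(2019, 4, 19), "sm"), abs=1e-9
            )

    def test_default_site_protocol_counts(self):
        cfg = ScenarioConfig()
        assert cfg.n_irrigated == 25 and cfg.n_rainfed == 20
        assert cfg.n_sites == 45

    def test_roles_reproducible_and_correctly_sized(self, scenario):
        df = generate_truth(SMALL).sample_field_measurements()
        again = Scenario(SMALL).sample_field_measurements()
        assert (df.role == again.role).all()
        by = df.groupby(["regime", "role"]).size()
        assert by.loc[("irrigated", "cal")] == SMALL.n_cal_irrigated
        assert by.loc[("rain_fed", "cal")] == SMALL.n_cal_rainfed
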