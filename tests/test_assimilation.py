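import datetime as dt
from dataclasses import replace

import numpy as np
import pytest

from wheatda.assimilation import (
    AssimilationConfig,
    CropAssimilationModel,
    EnsembleState,
    Observation,
    ObservationOperator,
    assimilate,
    enkf_update,
    make_observation,
    perturb_ensemble,
)
from wheatda.crop_model import CropState, SoilProfile

OBS_DATE = dt.date(2019, 4, 1)
H1 = np.array([[1.0]])


class TestPerturbEnsemble:
    def test_vanishing_sd_reproduces_the_state(self, soil):
        state = CropState(day=0, lai=2.0, theta=np.full(soil.n_layers, 0.25))
        ens = perturb_ensemble(state, 50, np.random.default_rng(0), 1e-12, 1e-12, soil)
        np.testing.assert_allclose(ens.members[:, 0], 2.0, rtol=1e-9)
        np.testing.assert_allclose(ens.members[:, 1:], 0.25, rtol=1e-9)

    def test_sample_spread_matches_requested_sd(self, soil):
        state = CropState(day=0, lai=3.0, theta=np.full(soil.n_layers, 0.25))
        n, sd = 500, 0.17
        ens = perturb_ensemble(state, n, np.random.default_rng(1), sd, 0.09, soil)
        rel_sd = ens.members[:, 0].std(ddof=1) / 3.0
        assert abs(rel_sd - sd) < 3 * sd / np.sqrt(2 * (n - 1))

    def test_reproducible_under_seed(self, soil):
        state = CropState(day=0, lai=1.0, theta=np.full(soil.n_layers, 0.2))
        a = perturb_ensemble(state, 20, np.random.default_rng(5), soil=soil)
        b = perturb_ensemble(state, 20, np.random.default_rng(5), soil=soil)
        np.testing.assert_array_equal(a.members, b.members)


class TestEnKFUpdate:
    def test_hand_worked_scalar_update(self):
        """Members {1,2,3}, obs 4 with sd 1: P=1, gain 1/2, mean 2 -> 3."""
        fc = EnsembleState(np.array([[1.0], [2.0], [3.0]]))
        obs = [Observation(OBS_DATE, "LAI", 4.0, 1.0)]
        an = enkf_update(fc, obs, H1, np.random.default_rng(0), perturb_obs=False)
        assert an.members.mean() == pytest.approx(3.0)
        np.testing.assert_allclose(an.members.ravel(), [2.5, 3.0, 3.5])

    def test_zero_gain_limit(self):
        fc = EnsembleState(np.array([[1.0], [2.0], [3.0]]))
        obs = [Observation(OBS_DATE, "LAI", 4.0, 1e8)]
        an = enkf_update(fc, obs, H1, np.random.default_rng(0), perturb_obs=False)
        assert an.members.mean() == pytest.approx(2.0, abs=1e-6)

    def test_full_trust_limit_pulls_to_observation(self):
        rng = np.random.default_rng(2)
        fc = EnsembleState(rng.normal(3.0, 0.5, (200, 1)))
        obs = [Observation(OBS_DATE, "LAI", 4.0, 1e-6)]
        an = enkf_update(fc, obs, H1, rng)
        assert an.members.mean() == pytest.approx(4.0, abs=1e-3)

    def test_analysis_variance_not_above_forecast_variance(self):
        rng = np.random.default_rng(3)
        fc = EnsembleState(rng.normal(3.0, 1.0, (500, 1)))
        obs = [Observation(OBS_DATE, "LAI", 4.0, 0.5)]
        an = enkf_update(fc, obs, H1, rng)
        assert an.members.var(ddof=1) <= fc.members.var(ddof=1) * (1 + 1e-9)

    def test_matches_exact_kalman_filter_at_large_ensemble(self):
        rng = np.random.default_rng(4)
        n, prior_mu, prior_sd, obs_v, obs_sd = 5000, 2.0, 1.0, 3.0, 0.5
        fc = EnsembleState(rng.normal(prior_mu, prior_sd, (n, 1)))
        an = enkf_update(fc, [Observation(OBS_DATE, "LAI", obs_v, obs_sd)], H1, rng)
        gain = prior_sd**2 / (prior_sd**2 + obs_sd**2)
        mu_exact = prior_mu + gain * (obs_v - prior_mu)
        var_exact = (1 - gain) * prior_sd**2
        se_mean = np.sqrt(var_exact / n)
        assert abs(an.members.mean() - mu_exact) < 3 * se_mean
        se_var = var_exact * np.sqrt(2.0 / (n - 1))
        assert abs(an.members.var(ddof=1) - var_exact) < 3 * se_var

    def test_member_count_conserved_and_finite(self, soil):
        rng = np.random.default_rng(6)
        H = ObservationOperator(soil)
        members = np.column_stack(
            [rng.uniform(0, 5, 40), rng.uniform(0.1, 0.4, (40, soil.n_layers))]
        )
        obs = [
            Observation(OBS_DATE, "LAI", 3.0, 0.4),
            Observation(OBS_DATE, "SM", 0.25, 0.02),
        ]
        an = enkf_update(EnsembleState(members), obs, H, rng, soil=soil)
        assert an.members.shape == members.shape
        assert np.all(np.isfinite(an.members))
        assert np.all(an.members[:, 0] >= 0)
        assert np.all(an.members[:, 1:] <= soil.theta_sat[None, :] + 1e-12)

    def test_requires_forecast_role(self):
        ens = EnsembleState(np.ones((3, 1)), role="analysis")
        with pytest.raises(ValueError):
            enkf_update(ens, [Observation(OBS_DATE, "LAI", 1.0, 1.0)], H1,
                        np.random.default_rng(0))


@pytest.fixture(scope="module")
def obs_seq():
    cfg = AssimilationConfig(n_ensemble=40, seed=11)
    dates = [dt.date(2019, 3, 17), dt.date(2019, 4, 16), dt.date(2019, 5, 13)]
    obs = [make_observation(d, "LAI", v, cfg) for d, v in zip(dates, (2.5, 6.0, 6.3))]
    obs += [make_observation(dates[1], "SM", 0.24, cfg)]
    return cfg, obs


class TestSequentialAssimilation:
    def test_no_observations_reduces_to_open_loop_mean(
        self, soil, params, rainfed_mgmt, weather
    ):
        cfg = AssimilationConfig(n_ensemble=60, seed=3)
        with pytest.warns(UserWarning, match="open-loop"):
            res = assimilate(soil, weather, rainfed_mgmt, params, 0.25, [], cfg)
        assert len(res.updates) == 0
        # ensemble mean stays near the unperturbed run (Monte Carlo spread only)
        ol = res.open_loop_series("lai")
        s = res.series("lai").reindex(ol.index).dropna()
        assert np.nanmax(np.abs(s - ol.loc[s.index])) < 0.6

    def test_joint_with_lai_only_observations_equals_lai_only_strategy(
        self, soil, params, rainfed_mgmt, weather, obs_seq
    ):
        cfg, obs = obs_seq
        lai_obs = [o for o in obs if o.kind == "LAI"]
        a = assimilate(soil, weather, rainfed_mgmt, params, 0.25, lai_obs,
                       replace(cfg, strategy="joint"))
        b = assimilate(soil, weather, rainfed_mgmt, params, 0.25, lai_obs,
                       replace(cfg, strategy="LAI_only"))
        np.testing.assert_array_equal(
            a.trajectory["lai"].to_numpy(), b.trajectory["lai"].to_numpy()
        )
        np.testing.assert_array_equal(a.member_yields, b.member_yields)

    def test_strategy_filtering_drops_other_kind(
        self, soil, params, rainfed_mgmt, weather, obs_seq
    ):
        cfg, obs = obs_seq
        model = CropAssimilationModel(
            obs, weather, soil, rainfed_mgmt, params, 0.25,
            replace(cfg, strategy="SM_only"),
        )
        assert {o.kind for o in model.observations} == {"SM"}

    def test_reproducible_under_config_seed(
        self, soil, params, rainfed_mgmt, weather, obs_seq
    ):
        cfg, obs = obs_seq
        a = assimilate(soil, weather, rainfed_mgmt, params, 0.25, obs, cfg)
        b = assimilate(soil, weather, rainfed_mgmt, params, 0.25, obs, cfg)
        np.testing.assert_array_equal(a.member_yields, b.member_yields)
        np.testing.assert_array_equal(
            a.trajectory["lai"].to_numpy(), b.trajectory["lai"].to_numpy()
        )

    def test_observation_outside_season_rejected(
        self, soil, params, rainfed_mgmt, weather
    ):
        cfg = AssimilationConfig(n_ensemble=10)
        bad = [make_observation(dt.date(2020, 1, 1), "LAI", 2.0, cfg)]
        with pytest.raises(ValueError, match="outside"):
            assimilate(soil, weather, rainfed_mgmt, params, 0.25, bad, cfg)

    def test_updates_pull_toward_observations(
        self, soil, params, rainfed_mgmt, weather, obs_seq
    ):
        """Analysis mean moves from the forecast toward the observed value."""
        cfg, obs = obs_seq
        res = assimilate(soil, weather, rainfed_mgmt, params, 0.25, obs,
                         replace(cfg, strategy="LAI_only"))
        by_date = {o.date: o.value for o in obs if o.kind == "LAI"}
        for u in res.updates:
            f, a = u.forecast_mean[0], u.analysis_mean[0]
            v = by_date[u.date]
            assert abs(a - v) <= abs(f - v) + 1e-9

    def test_summary_mentions_strategy_and_yield(
        self, soil, params, rainfed_mgmt, weather, obs_seq
    ):
        cfg, obs = obs_seq
        res = assimilate(soil, weather, rainfed_mgmt, params, 0.25, obs, cfg)
        text = res.summary()
        assert "joint" in text and "yield" in text


def test_config_validation():
    with pytest.raises(ValueError):
        AssimilationConfig(n_ensemble=1)
    with pytest.raises(ValueError):
        AssimilationConfig(strategy="both")
    with pytest.raises(ValueError):
        Observation(OBS_DATE, "LAI", 1.0, 0.0)
    with pytest.raises(ValueError):
        Observation(OBS_DATE, "ET", 1.0, 0.1)
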