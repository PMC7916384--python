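"""Ensemble Kalman filter assimilation of retrieved LAI and soil moisture
into the daily crop model.

The state vector per ensemble member is [LAI, theta_1..theta_L].  Members are
propagated day by day through the crop model; at each observation date a
multiplicative model-error perturbation (relative SDs for simulated LAI and
soil moisture) is applied to form the forecast set, and the stochastic
(perturbed-observation) Kalman update is applied with the retrieved LAI
and/or 0-20 cm soil moisture.  Cross-covariances in the joint strategy let a
soil-moisture observation move LAI (and deeper layers) and vice versa, which
is what distinguishes joint assimilation from running the two single-variable
strategies side by side.

Surface: :class:`CropAssimilationModel` (data in) -> ``fit()`` ->
:class:`AssimilationResults` (assimilated trajectory, open-loop baseline,
per-member yields, diagnostics, ``summary()``).  The functional wrapper
:func:`assimilate` mirrors the same contract.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crop_model as cm
from .crop_model import (
    CropParams,
    CropState,
    Management,
    SoilProfile,
    Stage,
    Trajectory,
    WeatherDay,
    _depth_weights,
)

logger = logging.getLogger(__name__)

STRATEGIES = ("LAI_only", "SM_only", "joint")

#: relative model/observation error SDs (fractions of the state value)
SD_MODEL_LAI = 0.17
SD_MODEL_SM = 0.09
SD_OBS_LAI = 0.13
SD_OBS_SM = 0.08


@dataclass(frozen=True)
class AssimilationConfig:
    n_ensemble: int = 100
    sd_model_lai: float = SD_MODEL_LAI
    sd_model_sm: float = SD_MODEL_SM
    sd_obs_lai: float = SD_OBS_LAI
    sd_obs_sm: float = SD_OBS_SM
    strategy: str = "joint"
    seed: int = 0
    obs_sd_floor: float = 0.01  # absolute floor on observation SD

    def __post_init__(self) -> None:
        if self.n_ensemble < 2:
            raise ValueError("n_ensemble must be >= 2")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        for name in ("sd_model_lai", "sd_model_sm", "sd_obs_lai", "sd_obs_sm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Observation:
    """A dated retrieved LAI (m2 m-2) or topsoil moisture SM (cm3 cm-3)."""

    date: dt.date
    kind: str  # "LAI" | "SM"
    value: float
    sd: float

    def __post_init__(self) -> None:
        if self.kind not in ("LAI", "SM"):
            raise ValueError("kind must be 'LAI' or 'SM'")
        if self.value < 0:
            raise ValueError("observation value must be >= 0")
        if self.sd <= 0:
            raise ValueError("observation sd must be positive")


def make_observation(
    date: dt.date, kind: str, value: float, cfg: AssimilationConfig
) -> Observation:
    """Observation with SD = relative SD x value, floored at cfg.obs_sd_floor."""
    rel = cfg.sd_obs_lai if kind == "LAI" else cfg.sd_obs_sm
    return Observation(date, kind, float(value), max(rel * float(value), cfg.obs_sd_floor))


@dataclass
class EnsembleState:
    """Members as rows of [lai, theta_1..theta_L]; role 'forecast' or 'analysis'."""

    members: np.ndarray
    role: str = "forecast"
    time_index: int = 0

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=float)
        if self.members.ndim != 2:
            raise ValueError("members must be an (n, d) matrix")
        if self.role not in ("forecast", "analysis"):
            raise ValueError("role must be 'forecast' or 'analysis'")

    @property
    def n(self) -> int:
        return self.members.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.members.mean(axis=0)


class ObservationOperator:
    """Linear map H from the state vector to observation space.

    LAI observations select the first component; SM observations aggregate
    layered moisture to the topsoil (default 0-20 cm) thickness-weighted mean.
    """

    def __init__(self, soil: SoilProfile, sm_depth: float = 20.0):
        self.soil = soil
        self.sm_depth = sm_depth
        self._lai_row = np.concatenate([[1.0], np.zeros(soil.n_layers)])
        self._sm_row = np.concatenate([[0.0], _depth_weights(soil.layer_depths, sm_depth)])

    def matrix(self, kinds: list[str]) -> np.ndarray:
        rows = []
        for k in kinds:
            if k == "LAI":
                rows.append(self._lai_row)
            elif k == "SM":
                rows.append(self._sm_row)
            else:
                raise ValueError(f"unknown observation kind {k!r}")
        return np.array(rows)


def perturb_ensemble(
    state: CropState,
    n: int,
    rng: np.random.Generator,
    sd_lai: float = SD_MODEL_LAI,
    sd_sm: float = SD_MODEL_SM,
    soil: SoilProfile | None = None,
) -> EnsembleState:
    """Monte Carlo ensemble around a state: lai*(1+eps), theta*(1+eps'), clamped."""
    if n < 2:
        raise ValueError("need n >= 2 members")
    lai = state.lai * (1.0 + rng.normal(0.0, sd_lai, size=n))
    theta = state.theta[None, :] * (1.0 + rng.normal(0.0, sd_sm, size=(n, len(state.theta))))
    members = np.column_stack([lai, theta])
    return EnsembleState(_clamp_members(members, soil), role="forecast")


def _clamp_members(members: np.ndarray, soil: SoilProfile | None) -> np.ndarray:
    members = np.array(members, dtype=float)
    members[:, 0] = np.clip(members[:, 0], 0.0, None)
    hi = soil.theta_sat if soil is not None else 1.0
    members[:, 1:] = np.clip(members[:, 1:], 0.0, hi)
    if np.any(~np.isfinite(members)):
        raise FloatingPointError("non-finite ensemble member after clamping")
    return members


def enkf_update(
    forecast: EnsembleState,
    obs: list[Observation],
    H: ObservationOperator | np.ndarray,
    rng: np.random.Generator,
    perturb_obs: bool = True,
    soil: SoilProfile | None = None,
) -> EnsembleState:
    """Stochastic EnKF analysis step.

    Each member's innovation uses its own observation draw N(value, sd^2)
    (``perturb_obs=False`` gives the deterministic unperturbed-observation
    variant used in unit tests).  The forecast covariance is the ensemble
    sample covariance; a singular innovation covariance is regularised by
    inflating the R diagonal.
    """
    if forecast.role != "forecast":
        raise ValueError("enkf_update expects a forecast ensemble")
    if not obs:
        raise ValueError("no observations supplied")
    X = np.array(forecast.members, dtype=float)
    n, d = X.shape
    kinds = [o.kind for o in obs]
    Hm = H.matrix(kinds) if isinstance(H, ObservationOperator) else np.asarray(H, dtype=float)
    m = Hm.shape[0]
    values = np.array([o.value for o in obs])
    sds = np.array([o.sd for o in obs])
    R = np.diag(sds**2)

    S = X @ Hm.T  # (n, m) state in observation space
    Xa = X - X.mean(axis=0)
    Sa = S - S.mean(axis=0)
    cov_xs = Xa.T @ Sa / (n - 1)  # (d, m)
    cov_ss = Sa.T @ Sa / (n - 1) + R  # (m, m)
    try:
        K = np.linalg.solve(cov_ss.T, cov_xs.T).T  # (d, m) Kalman gain
    except np.linalg.LinAlgError:
        eps = 1e-10 * max(np.trace(cov_ss) / m, 1.0)
        logger.warning("singular innovation covariance; inflating R diagonal by %g", eps)
        K = np.linalg.solve((cov_ss + eps * np.eye(m)).T, cov_xs.T).T

    if perturb_obs:
        D = values[None, :] + rng.normal(0.0, 1.0, size=(n, m)) * sds[None, :]
    else:
        D = np.broadcast_to(values, (n, m))
    updated = X + (D - S) @ K.T
    return EnsembleState(_clamp_members(updated, soil), role="analysis", time_index=forecast.time_index)


# ---------------------------------------------------------------------------
# Model / Results surface


@dataclass
class UpdateRecord:
    date: dt.date
    kinds: list
    forecast_mean: np.ndarray
    analysis_mean: np.ndarray
    forecast_sd: np.ndarray
    analysis_sd: np.ndarray


class CropAssimilationModel:
    """Crop growth model + observation sequence, fitted by sequential EnKF.

    Parameters
    ----------
    observations : list of Observation (any mix of LAI and SM kinds)
    weather, soil, management, params, init_theta : crop-model inputs
    config : AssimilationConfig (ensemble size, error SDs, strategy, seed)
    """

    def __init__(
        self,
        observations: list[Observation],
        weather: list[WeatherDay],
        soil: SoilProfile,
        management: Management,
        params: CropParams,
        init_theta,
        config: AssimilationConfig = AssimilationConfig(),
    ):
        self.config = config
        self.soil = soil
        self.management = management
        self.params = params
        self.weather = weather
        self.init_theta = np.broadcast_to(
            np.asarray(init_theta, dtype=float), (soil.n_layers,)
        ).copy()
        self.observations = self._filter_strategy(observations, config.strategy)
        self.H = ObservationOperator(soil)

    @classmethod
    def from_frames(
        cls,
        obs_df: pd.DataFrame,
        weather_df: pd.DataFrame,
        soil: SoilProfile,
        management: Management,
        params: CropParams,
        init_theta,
        config: AssimilationConfig = AssimilationConfig(),
    ) -> "CropAssimilationModel":
        """Build from a date,kind,value[,sd] observation table and a weather table."""
        obs = []
        for row in obs_df.itertuples(index=False):
            date = row.date
            if isinstance(date, str):
                date = dt.date.fromisoformat(date)
            elif isinstance(date, pd.Timestamp):
                date = date.date()
            sd = getattr(row, "sd", None)
            if sd is None or (isinstance(sd, float) and np.isnan(sd)):
                obs.append(make_observation(date, row.kind, row.value, config))
            else:
                obs.append(Observation(date, row.kind, float(row.value), float(sd)))
        return cls(
            obs, cm.weather_from_frame(weather_df), soil, management, params, init_theta, config
        )

    @staticmethod
    def _filter_strategy(obs: list[Observation], strategy: str) -> list[Observation]:
        if strategy == "LAI_only":
            obs = [o for o in obs if o.kind == "LAI"]
        elif strategy == "SM_only":
            obs = [o for o in obs if o.kind == "SM"]
        return sorted(obs, key=lambda o: (o.date, o.kind))

    def fit(self, open_loop: Trajectory | None = None) -> "AssimilationResults":
        """Run the sequential filter.

        `open_loop` may carry a precomputed no-assimilation baseline
        trajectory (it is recomputed here otherwise).
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        if not self.observations:
            warnings.warn("no observations after strategy filtering: open-loop ensemble only")
        by_date: dict[dt.date, list[Observation]] = {}
        for o in self.observations:
            by_date.setdefault(o.date, []).append(o)

        season = sorted(
            (d for d in self.weather if d.date >= self.management.sowing_date),
            key=lambda d: d.date,
        )
        if not season or season[0].date != self.management.sowing_date:
            raise ValueError(f"missing weather for date {self.management.sowing_date}")
        for o in self.observations:
            if not (season[0].date <= o.date <= season[-1].date):
                raise ValueError(f"observation on {o.date} outside the simulated season")

        n, L = cfg.n_ensemble, self.soil.n_layers
        # initial ensemble: perturb the initial state with the model-error SDs
        init = CropState(day=0, lai=self.params.lai_init, theta=self.init_theta)
        ens = perturb_ensemble(
            init, n, rng, cfg.sd_model_lai, cfg.sd_model_sm, self.soil
        )
        lai = ens.members[:, 0].copy()
        theta = ens.members[:, 1:].copy()
        gdd = np.zeros(n)
        biomass = np.zeros(n)

        dates, mean_lai, mean_sm, sd_lai_h, sd_sm_h, mean_theta = [], [], [], [], [], []
        member_theta_w = _depth_weights(self.soil.layer_depths, 20.0)
        updates: list[UpdateRecord] = []
        expected = self.management.sowing_date
        fill_sum = np.zeros(n)
        fill_days = np.zeros(n)
        k = 0
        for day in season:
            if day.date != expected:
                raise ValueError(f"missing weather for date {expected}")
            expected = expected + dt.timedelta(days=1)
            out = cm.advance_day(
                lai,
                theta,
                gdd,
                biomass,
                day,
                self.soil,
                self.management.irrigation_on(day.date),
                self.params,
            )
            lai, theta, gdd, biomass = out["lai"], out["theta"], out["gdd"], out["biomass"]
            filling = out["stage"] == Stage.MILKING
            fill_sum += np.where(filling, out["stress"], 0.0)
            fill_days += filling

            todays = by_date.get(day.date)
            if todays:
                members = np.column_stack([lai, theta])
                # model-error perturbation forms the forecast set at time k
                pert = np.column_stack(
                    [
                        1.0 + rng.normal(0.0, cfg.sd_model_lai, size=n),
                        1.0 + rng.normal(0.0, cfg.sd_model_sm, size=(n, L)),
                    ]
                )
                forecast = EnsembleState(
                    _clamp_members(members * pert, self.soil), role="forecast", time_index=k
                )
                analysis = enkf_update(forecast, todays, self.H, rng, soil=self.soil)
                Hm = self.H.matrix([o.kind for o in todays])
                updates.append(
                    UpdateRecord(
                        date=day.date,
                        kinds=[o.kind for o in todays],
                        forecast_mean=(forecast.members @ Hm.T).mean(axis=0),
                        analysis_mean=(analysis.members @ Hm.T).mean(axis=0),
                        forecast_sd=(forecast.members @ Hm.T).std(axis=0, ddof=1),
                        analysis_sd=(analysis.members @ Hm.T).std(axis=0, ddof=1),
                    )
                )
                lai = analysis.members[:, 0].copy()
                theta = analysis.members[:, 1:].copy()
                k += 1

            dates.append(day.date)
            mean_lai.append(lai.mean())
            sd_lai_h.append(lai.std(ddof=1))
            sm = theta @ member_theta_w
            mean_sm.append(sm.mean())
            sd_sm_h.append(sm.std(ddof=1))
            mean_theta.append(theta.mean(axis=0))
            if out["stage"].min() >= Stage.MATURE:
                break

        fill_stress = np.where(fill_days > 0, fill_sum / np.maximum(fill_days, 1), 1.0)
        member_yields = cm.effective_harvest_index(self.params, fill_stress) * biomass
        if open_loop is None:
            open_loop = cm.simulate(
                self.soil, self.weather, self.management, self.params, self.init_theta
            )
        traj = pd.DataFrame(
            {
                "date": dates,
                "lai": mean_lai,
                "theta_0_20": mean_sm,
                "lai_sd": sd_lai_h,
                "theta_0_20_sd": sd_sm_h,
            }
        )
        return AssimilationResults(
            model=self,
            trajectory=traj,
            theta_mean=np.array(mean_theta),
            open_loop=open_loop,
            member_yields=member_yields,
            updates=updates,
        )


class AssimilationResults:
    """Output of one assimilation run.

    Attributes
    ----------
    trajectory : daily DataFrame of the ensemble-mean assimilated LAI and
        0-20 cm soil moisture with ensemble SDs.
    open_loop : the unperturbed single-model Trajectory (no updates).
    member_yields : per-member final yields (kg ha-1).
    updates : per-observation-date forecast/analysis diagnostics.
    """

    def __init__(self, model, trajectory, theta_mean, open_loop, member_yields, updates):
        self.model = model
        self.trajectory = trajectory
        self.theta_mean = theta_mean
        self.open_loop = open_loop
        self.member_yields = np.asarray(member_yields, dtype=float)
        self.updates = updates

    @property
    def yield_mean(self) -> float:
        return float(self.member_yields.mean())

    @property
    def yield_sd(self) -> float:
        return float(self.member_yields.std(ddof=1))

    def series(self, var: str = "lai") -> pd.Series:
        col = "lai" if var.lower() == "lai" else "theta_0_20"
        return self.trajectory.set_index("date")[col]

    def open_loop_series(self, var: str = "lai") -> pd.Series:
        df = self.open_loop.to_dataframe().set_index("date")
        return df["lai" if var.lower() == "lai" else "theta_0_20"]

    def value_at(self, date: dt.date, var: str = "lai") -> float:
        s = self.series(var)
        if date not in s.index:
            raise KeyError(f"no assimilated state on {date}")
        return float(s.loc[date])

    def rmse_vs(self, truth: pd.Series, var: str = "lai", dates=None) -> float:
        """Time-mean RMSE of the assimilated series against a dated truth series."""
        est = self.series(var)
        idx = est.index.intersection(truth.index)
        if dates is not None:
            idx = idx.intersection(pd.Index(dates))
        if len(idx) == 0:
            raise ValueError("no overlapping dates with the truth series")
        d = est.loc[idx].to_numpy() - truth.loc[idx].to_numpy()
        return float(np.sqrt(np.mean(d**2)))

    def open_loop_rmse_vs(self, truth: pd.Series, var: str = "lai", dates=None) -> float:
        est = self.open_loop_series(var)
        idx = est.index.intersection(truth.index)
        if dates is not None:
            idx = idx.intersection(pd.Index(dates))
        d = est.loc[idx].to_numpy() - truth.loc[idx].to_numpy()
        return float(np.sqrt(np.mean(d**2)))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Crop data assimilation (ensemble Kalman filter)",
            "=" * 48,
            f"strategy:          {cfg.strategy}",
            f"ensemble size:     {cfg.n_ensemble}",
            f"model error SDs:   LAI {cfg.sd_model_lai:.0%}, SM {cfg.sd_model_sm:.0%}",
            f"obs error SDs:     LAI {cfg.sd_obs_lai:.0%}, SM {cfg.sd_obs_sm:.0%}",
            f"updates applied:   {len(self.updates)}",
            f"assimilated yield: {self.yield_mean:.1f} +/- {self.yield_sd:.1f} kg ha-1",
            f"open-loop yield:   {self.open_loop.yield_:.1f} kg ha-1",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, var: str = "lai"):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.series(var)
        ol = self.open_loop_series(var)
        sd = self.trajectory.set_index("date")[
            "lai_sd" if var.lower() == "lai" else "theta_0_20_sd"
        ]
        ax.plot(ol.index, ol.values, label="open loop", color="0.6")
        ax.plot(s.index, s.values, label="assimilated", color="C0")
        ax.fill_between(s.index, s - sd, s + sd, alpha=0.25, color="C0")
        for u in self.updates:
            ax.axvline(u.date, color="0.85", lw=0.5, zorder=0)
        ax.set_ylabel("LAI (m2 m-2)" if var.lower() == "lai" else "theta 0-20 cm (cm3 cm-3)")
        ax.legend()
        return ax


def assimilate(
    soil: SoilProfile,
    weather: list[WeatherDay],
    management: Management,
    params: CropParams,
    init_theta,
    obs_sequence: list[Observation],
    cfg: AssimilationConfig,
) -> AssimilationResults:
    """Functional wrapper: build a CropAssimilationModel and fit it."""
    return CropAssimilationModel(
        obs_sequence, weather, soil, management, params, init_theta, cfg
    ).fit()
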