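"""Synthetic scenario generator for end-to-end twin experiments.

Generates every input the pipeline consumes — daily weather, terrain, truth
LAI/soil-moisture/yield trajectories per field site, optical and SAR scenes,
and noisy field samples — with the statistical structure the analysis
assumes.  Scenes are rendered through the *inverse* of the retrieval chain
(NDVI-LAI regression, NDWI-m_veg quadratic, water cloud model, backscatter-
moisture regression) plus sensor noise, so a zero-noise render/retrieve
round trip is exact by construction and the assimilation and yield stages
are the components actually under test.

The default scenario emulates a warm-temperate semi-arid winter-wheat
season (October sowing, June harvest, ~300 mm in-season rainfall): 25
irrigated sites on a dense supplemental-irrigation schedule that keeps the
crop effectively unstressed, and 20 rain-fed sites that develop spring
water-stress episodes.  Per-site cultivar/soil parameters and initial
moisture are jittered around the nominal values the assimilating model
uses, creating the realistic model error that assimilation corrects.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import retrieval as rt
from .area_classification import RegimeMask, TerrainGrid
from .crop_model import (
    CropParams,
    Management,
    SoilProfile,
    Trajectory,
    WeatherDay,
    simulate,
)
from .rasters import Raster
from .retrieval import MVEG_POLY, OpticalScene, SARScene

D = dt.date

#: dense supplemental-irrigation schedule keeping the irrigated regime
#: unstressed through the yield-forming window
DEFAULT_IRRIGATION = tuple(
    [(D(2018, 10, 15), 60.0), (D(2018, 11, 20), 60.0), (D(2019, 1, 10), 50.0)]
    + [(D(2019, 2, 10) + dt.timedelta(days=8 * i), 50.0) for i in range(16)]
)

#: optical (5-day constellation, cloud-screened) and SAR (12-day) scene dates
DEFAULT_S2_DATES = (
    D(2019, 3, 17), D(2019, 4, 1), D(2019, 4, 16),
    D(2019, 5, 11), D(2019, 5, 21), D(2019, 5, 26), D(2019, 6, 10),
)
DEFAULT_S1_DATES = (
    D(2019, 3, 2), D(2019, 3, 14), D(2019, 3, 26), D(2019, 4, 7),
    D(2019, 4, 19), D(2019, 5, 1), D(2019, 5, 13),
)
#: scene date standing for each phenophase in the stage composites
DEFAULT_STAGE_DATES_LAI = {
    "green_up": D(2019, 3, 17), "jointing": D(2019, 4, 1),
    "heading_filling": D(2019, 4, 16), "milking": D(2019, 5, 21),
}
DEFAULT_STAGE_DATES_SM = {
    "green_up": D(2019, 3, 2), "jointing": D(2019, 4, 7),
    "heading_filling": D(2019, 4, 19), "milking": D(2019, 5, 13),
}


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    n_irrigated: int = 25
    n_rainfed: int = 20
    grid_shape: tuple = (66, 60)  # includes a non-wheat background strip
    background_rows: int = 6
    pixel_size: float = 30.0  # m

    season_start: dt.date = D(2018, 10, 1)
    season_end: dt.date = D(2019, 6, 30)
    sowing_date: dt.date = D(2018, 10, 10)

    # weather: seasonal sinusoids + noise; Poisson-gamma rainfall
    temp_mean: float = 13.0  # °C annual mean
    temp_amp: float = 12.0  # °C annual amplitude (coldest mid-January)
    temp_phase_doy: int = 15
    diurnal_half_range: float = 4.5  # °C, tmax/tmin = T ± this
    temp_noise: float = 1.5
    srad_mean: float = 16.0  # MJ m-2 d-1
    srad_amp: float = 9.0
    srad_noise: float = 2.0
    precip_event_rate: float = 0.22  # events d-1 -> ~300 mm per season
    precip_mean_depth: float = 5.0  # mm per event
    precip_shape: float = 1.2  # gamma shape of event depths

    irrigation_schedule: tuple = DEFAULT_IRRIGATION

    s1_dates: tuple = DEFAULT_S1_DATES
    s2_dates: tuple = DEFAULT_S2_DATES
    cloud_masked_dates: tuple = ()
    stage_dates_lai: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_DATES_LAI))
    stage_dates_sm: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_DATES_SM))
    measurement_dates: tuple = (D(2019, 3, 17), D(2019, 4, 19))

    # sensor noise
    reflectance_sd: float = 0.04
    backscatter_sd_db: float = 1.9
    incidence_deg: float = 39.0
    # field-measurement noise
    meas_sd_lai: float = 0.3  # m2 m-2
    meas_sd_sm: float = 0.02  # cm3 cm-3
    meas_sd_yield: float = 300.0  # kg ha-1

    # rendering: plant water content tracks canopy as m_veg = a + b*LAI
    mveg_intercept: float = MVEG_POLY[2]
    mveg_per_lai: float = 0.35
    refl_band_sum: float = 0.5  # red + nir
    stubble_lai: float = 0.05  # post-harvest residual canopy
    background_theta: float = 0.18
    render_bias: float = 0.0  # model-mismatch knob on rendered NDVI/backscatter

    # per-site truth heterogeneity (relative SDs around the nominal values);
    # a common "fertility" factor scales canopy potential and radiation-use
    # efficiency together, so vigorous fields have both more leaf area and
    # more yield, while water-supply factors (field capacity, initial
    # moisture) vary independently
    fertility_cv: float = 0.10
    rgr_cv: float = 0.04
    lai_max_cv: float = 0.04
    rue_cv: float = 0.03
    senescence_cv: float = 0.10
    fc_cv: float = 0.09
    #: initial profile moisture as a fraction of each layer's field capacity
    #: (soils start the season near a common matric potential, so wetter-
    #: capacity soils hold proportionally more water)
    init_theta_frac_range: tuple = (0.75, 0.97)
    #: rainfall infiltration loss per degree of slope (surface runoff on
    #: sloping rain-fed fields), floored so every field keeps most rain
    runoff_per_degree: float = 0.02
    infiltration_floor: float = 0.55

    # terrain by regime
    elev_irrigated: tuple = (250.0, 550.0)
    elev_rainfed: tuple = (650.0, 1400.0)
    slope_irrigated: tuple = (0.5, 8.0)
    slope_rainfed: tuple = (2.0, 13.0)

    # calibration/validation split per regime
    n_cal_irrigated: int = 10
    n_cal_rainfed: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.background_rows < self.grid_shape[0]:
            raise ValueError("background_rows must fit inside the grid")
        for name in ("reflectance_sd", "backscatter_sd_db", "meas_sd_lai",
                     "meas_sd_sm", "meas_sd_yield"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in self.s1_dates + self.s2_dates:
            if not (self.season_start <= d <= self.season_end):
                raise ValueError(f"scene date {d} outside the season")

    @property
    def n_sites(self) -> int:
        return self.n_irrigated + self.n_rainfed


#: nominal crop parameters used both as truth centre and by the assimilating
#: model; green-up threshold and initial LAI give a canopy that clears the
#: NDVI=0.25 wheat-mask rule by mid-March
NOMINAL_PARAMS = CropParams(
    lai_init=0.6, rue=1.0, stage_gdd=(600.0, 895, 1120, 1495, 2030)
)
NOMINAL_SOIL = SoilProfile()
NOMINAL_INIT_THETA = 0.28


@dataclass
class TruthRecord:
    site_id: str
    regime: str
    trajectory: Trajectory
    management: Management
    soil: SoilProfile
    params: CropParams
    init_theta: float
    elevation: float
    slope: float

    def series(self, var: str = "lai") -> pd.Series:
        df = self.trajectory.to_dataframe().set_index("date")
        return df["lai" if var.lower() == "lai" else "theta_0_20"]

    def value_at(self, date: dt.date, var: str, stubble_lai: float = 0.05) -> float:
        """Truth state on `date`; post-maturity LAI falls to crop stubble and
        moisture holds at its final value."""
        s = self.series(var)
        if date in s.index:
            return float(s.loc[date])
        if date > s.index.max():
            return stubble_lai if var.lower() == "lai" else float(s.iloc[-1])
        raise KeyError(f"truth not available on {date}")


def generate_weather(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> list[WeatherDay]:
    """Sinusoidal temperature/radiation seasonality plus Poisson-gamma rainfall."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = []
    d = cfg.season_start
    while d <= cfg.season_end:
        doy = d.timetuple().tm_yday
        phase = 2 * np.pi * (doy - cfg.temp_phase_doy) / 365.25
        t = cfg.temp_mean - cfg.temp_amp * np.cos(phase) + rng.normal(0, cfg.temp_noise)
        srad = max(
            0.5, cfg.srad_mean - cfg.srad_amp * np.cos(phase) + rng.normal(0, cfg.srad_noise)
        )
        rain = 0.0
        if cfg.precip_event_rate > 0 and rng.random() < cfg.precip_event_rate:
            rain = float(rng.gamma(cfg.precip_shape, cfg.precip_mean_depth / cfg.precip_shape))
        out.append(
            WeatherDay(d, t + cfg.diurnal_half_range, t - cfg.diurnal_half_range, rain, srad)
        )
        d += dt.timedelta(days=1)
    return out


def weather_to_frame(wx: list[WeatherDay]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [w.date.isoformat() for w in wx],
            "tmax": [w.tmax for w in wx],
            "tmin": [w.tmin for w in wx],
            "precip": [w.precip for w in wx],
            "srad": [w.srad for w in wx],
        }
    )


class Scenario:
    """A generated study region: weather, per-site truths, terrain and layout.

    The wheat area is tiled into one rectangular field patch per site below a
    non-wheat background strip; `field_ids` maps pixels to site indices
    (-1 = background).
    """

    def __init__(self, cfg: ScenarioConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.weather = generate_weather(cfg, rng)
        self._layout(cfg)
        self._truths(cfg, rng)
        self._terrain(cfg, rng)

    # -- construction ----------------------------------------------------

    def _layout(self, cfg: ScenarioConfig) -> None:
        nrow, ncol = cfg.grid_shape
        wheat_rows = nrow - cfg.background_rows
        # tile the wheat area into ~square blocks, one per site
        n_r = int(np.floor(np.sqrt(cfg.n_sites * wheat_rows / ncol))) or 1
        n_c = int(np.ceil(cfg.n_sites / n_r))
        row_edges = np.linspace(cfg.background_rows, nrow, n_r + 1).astype(int)
        col_edges = np.linspace(0, ncol, n_c + 1).astype(int)
        ids = np.full(cfg.grid_shape, -1, dtype=int)
        k = 0
        blocks = []
        for i in range(n_r):
            for j in range(n_c):
                if k >= cfg.n_sites:
                    break
                ids[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = k
                blocks.append((row_edges[i], row_edges[i + 1], col_edges[j], col_edges[j + 1]))
                k += 1
        self.field_ids = Raster(ids.astype(float), cfg.pixel_size)
        self.blocks = blocks

    def _truths(self, cfg: ScenarioConfig, rng: np.random.Generator) -> None:
        regimes = ["irrigated"] * cfg.n_irrigated + ["rain_fed"] * cfg.n_rainfed
        rng.shuffle(regimes)
        self.truths: list[TruthRecord] = []
        for k, regime in enumerate(regimes):
            if regime == "irrigated":
                elev = rng.uniform(*cfg.elev_irrigated)
                slope = rng.uniform(*cfg.slope_irrigated)
            else:
                elev = rng.uniform(*cfg.elev_rainfed)
                slope = rng.uniform(*cfg.slope_rainfed)
            fertility = 1 + rng.normal(0, cfg.fertility_cv)
            params = replace(
                NOMINAL_PARAMS,
                rgr=NOMINAL_PARAMS.rgr * (1 + rng.normal(0, cfg.rgr_cv)),
                lai_max=NOMINAL_PARAMS.lai_max
                * max(fertility * (1 + rng.normal(0, cfg.lai_max_cv)), 0.3),
                rue=NOMINAL_PARAMS.rue
                * max(fertility * (1 + rng.normal(0, cfg.rue_cv)), 0.3),
                senescence_rate=NOMINAL_PARAMS.senescence_rate
                * (1 + rng.normal(0, cfg.senescence_cv)),
            )
            fc_scale = 1 + rng.normal(0, cfg.fc_cv)
            soil = SoilProfile(
                layer_depths=NOMINAL_SOIL.layer_depths,
                theta_fc=np.clip(NOMINAL_SOIL.theta_fc * fc_scale, 0.2, 0.42),
                theta_wp=NOMINAL_SOIL.theta_wp,
                theta_sat=NOMINAL_SOIL.theta_sat,
                infiltration_frac=max(
                    1.0 - cfg.runoff_per_degree * slope, cfg.infiltration_floor
                ),
            )
            init_frac = rng.uniform(*cfg.init_theta_frac_range)
            init_theta = init_frac * soil.theta_fc
            mgmt = Management(
                cfg.sowing_date,
                irrigation_events=cfg.irrigation_schedule if regime == "irrigated" else (),
            )
            traj = simulate(soil, self.weather, mgmt, params, init_theta)
            self.truths.append(
                TruthRecord(
                    site_id=f"S{k:02d}",
                    regime=regime,
                    trajectory=traj,
                    management=mgmt,
                    soil=soil,
                    params=params,
                    init_theta=float(np.mean(init_theta)),
                    elevation=float(elev),
                    slope=float(slope),
                )
            )
        # calibration/validation roles, seeded per regime
        self.roles = {}
        for regime, n_cal in (
            ("irrigated", cfg.n_cal_irrigated),
            ("rain_fed", cfg.n_cal_rainfed),
        ):
            idx = [t.site_id for t in self.truths if t.regime == regime]
            cal = set(rng.choice(idx, size=min(n_cal, len(idx)), replace=False))
            for sid in idx:
                self.roles[sid] = "cal" if sid in cal else "val"

    def _terrain(self, cfg: ScenarioConfig, rng: np.random.Generator) -> None:
        ids = self.field_ids.data.astype(int)
        elev = np.full(cfg.grid_shape, 500.0)
        slope = np.full(cfg.grid_shape, 3.0)
        for k, t in enumerate(self.truths):
            elev[ids == k] = t.elevation
            slope[ids == k] = t.slope
        elev += rng.normal(0, 3.0, size=cfg.grid_shape)
        slope = np.clip(slope + rng.normal(0, 0.3, size=cfg.grid_shape), 0.0, 45.0)
        self.terrain = TerrainGrid(
            Raster(elev, cfg.pixel_size), Raster(slope, cfg.pixel_size)
        )

    # -- truth rasters and rendered scenes --------------------------------

    def truth_raster(self, date: dt.date, var: str = "lai") -> Raster:
        cfg = self.cfg
        ids = self.field_ids.data.astype(int)
        out = np.empty(cfg.grid_shape)
        bg = 0.0 if var.lower() == "lai" else cfg.background_theta
        out[ids == -1] = bg
        for k, t in enumerate(self.truths):
            out[ids == k] = t.value_at(date, var, cfg.stubble_lai)
        return Raster(out, cfg.pixel_size)

    def regime_truth_mask(self) -> RegimeMask:
        ids = self.field_ids.data.astype(int)
        codes = np.zeros(self.cfg.grid_shape)
        for k, t in enumerate(self.truths):
            codes[ids == k] = 1 if t.regime == "irrigated" else 2
        return RegimeMask(Raster(codes, self.cfg.pixel_size))

    def render_optical(self, date: dt.date, rng: np.random.Generator | None = None) -> OpticalScene:
        """Reflectance scene whose noise-free NDVI/NDWI invert exactly to truth."""
        cfg = self.cfg
        if date in cfg.cloud_masked_dates:
            nan = Raster(np.full(cfg.grid_shape, np.nan), cfg.pixel_size)
            return OpticalScene(date, nan, nan, nan)
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        lai = self.truth_raster(date, "lai").data
        lm = rt.lai_model_from_coefficients()
        ndvi = (lai - lm.intercept) / lm.slope * (1 + cfg.render_bias)
        s = cfg.refl_band_sum
        red = s * (1 - ndvi) / 2
        nir = s * (1 + ndvi) / 2
        m_veg = cfg.mveg_intercept + cfg.mveg_per_lai * lai
        a, b, c = MVEG_POLY
        ndwi = (-b + np.sqrt(b**2 - 4 * a * (c - m_veg))) / (2 * a)
        mir = nir * (1 - ndwi) / (1 + ndwi)
        if cfg.reflectance_sd > 0:
            red = red + rng.normal(0, cfg.reflectance_sd, red.shape)
            nir = nir + rng.normal(0, cfg.reflectance_sd, nir.shape)
            mir = mir + rng.normal(0, cfg.reflectance_sd, mir.shape)
            red, nir, mir = (np.clip(x, 1e-3, 1.0) for x in (red, nir, mir))
        g = self.field_ids
        return OpticalScene(date, g.like(red), g.like(nir), g.like(mir))

    def render_sar(self, date: dt.date, rng: np.random.Generator | None = None) -> SARScene:
        """Backscatter scene from truth topsoil moisture through the forward
        water cloud model; wetter soil maps to stronger soil backscatter."""
        cfg = self.cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        theta = self.truth_raster(date, "sm").data
        lai = self.truth_raster(date, "lai").data
        sm_model = rt.sm_model_from_coefficients()
        sigma_soil_db = (theta - sm_model.intercept) / sm_model.slope * (1 + cfg.render_bias)
        m_veg = cfg.mveg_intercept + cfg.mveg_per_lai * lai
        sigma_can = rt.wcm_forward(
            rt.db_to_linear(sigma_soil_db), m_veg, cfg.incidence_deg
        )
        sigma_can_db = rt.linear_to_db(sigma_can)
        if cfg.backscatter_sd_db > 0:
            sigma_can_db = sigma_can_db + rng.normal(0, cfg.backscatter_sd_db, sigma_can_db.shape)
        return SARScene(date, self.field_ids.like(sigma_can_db), cfg.incidence_deg)

    # -- site-level sampling ----------------------------------------------

    def site_pixels(self, k: int) -> tuple:
        r0, r1, c0, c1 = self.blocks[k]
        return slice(r0, r1), slice(c0, c1)

    def sample_field_measurements(self, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Noisy LAI/SM at the two campaign dates plus yield, with cal/val roles."""
        cfg = self.cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
        rows = []
        for t in self.truths:
            row = {
                "site_id": t.site_id,
                "regime": t.regime,
                "role": self.roles[t.site_id],
                "yield": max(
                    0.0, t.trajectory.yield_ + rng.normal(0, cfg.meas_sd_yield)
                ),
            }
            for i, date in enumerate(cfg.measurement_dates, start=1):
                row[f"lai_{i}"] = max(0.0, t.value_at(date, "lai") + rng.normal(0, cfg.meas_sd_lai))
                row[f"sm_{i}"] = float(
                    np.clip(t.value_at(date, "sm") + rng.normal(0, cfg.meas_sd_sm), 0.0, 0.6)
                )
                row[f"date_{i}"] = date.isoformat()
            rows.append(row)
        return pd.DataFrame(rows)


def generate_truth(cfg: ScenarioConfig) -> Scenario:
    """Generate the full scenario (weather, truths, terrain, layout)."""
    return Scenario(cfg)
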