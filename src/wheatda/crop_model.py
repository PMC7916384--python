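"""Reduced-order daily winter-wheat growth and soil-water model.

This is a deliberately small surrogate for a full crop simulator of the
CERES-Wheat / DSSAT family: it carries exactly the observable states a
remote-sensing assimilation system needs — leaf area index (LAI) and layered
volumetric soil moisture — plus thermal time, phenophase, above-ground
biomass and final grain yield.  No claim of numeric equivalence with
CERES-Wheat is made; the dynamics are:

* phenology by accumulated growing degree days (GDD) over a base temperature,
  with five named stages (green-up, jointing, heading-filling, milking,
  maturity) triggered at fixed GDD thresholds;
* LAI growing logistically from green-up until the milking stage, scaled by a
  water-stress factor, then declining exponentially (senescence);
* a cascading-bucket soil water balance over seven layers: infiltration from
  rain plus irrigation fills each layer to field capacity and the excess
  drains downward; actual evapotranspiration is a Priestley–Taylor-style
  radiation-driven potential demand scaled by the stress factor and extracted
  from the root zone;
* biomass by radiation-use efficiency on intercepted radiation, yield as a
  fixed harvest index on biomass at maturity.

All daily updates are vectorised over an arbitrary leading "member" axis so
an ensemble can be propagated in one call (see :func:`advance_day`).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "WeatherDay",
    "SoilProfile",
    "Management",
    "CropParams",
    "CropState",
    "Trajectory",
    "thermal_time",
    "water_stress_factor",
    "potential_et",
    "advance_day",
    "step",
    "simulate",
    "root_zone_theta",
    "weather_from_frame",
]


class Stage(IntEnum):
    """Phenophase, ordered; transitions at the GDD thresholds in CropParams."""

    PRESOWING = 0  # sown but before spring green-up (overwinter)
    GREEN_UP = 1
    JOINTING = 2
    HEADING_FILLING = 3
    MILKING = 4
    MATURE = 5


@dataclass(frozen=True)
class WeatherDay:
    """One day of forcing: temperatures (°C), rain (mm), solar radiation (MJ m-2)."""

    date: dt.date
    tmax: float
    tmin: float
    precip: float
    srad: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"tmax < tmin on {self.date}")
        if self.precip < 0 or self.srad < 0:
            raise ValueError(f"negative precip or srad on {self.date}")


@dataclass(frozen=True)
class SoilProfile:
    """Layered soil hydraulic properties.

    Default layering follows the common 0-10, 10-20, 20-50, 50-80, 80-120,
    120-160, 160-200 cm field-sampling scheme.
    """

    layer_depths: np.ndarray = field(
        default_factory=lambda: np.array([10.0, 10, 30, 30, 40, 40, 40])
    )  # cm
    theta_fc: np.ndarray = field(default_factory=lambda: np.full(7, 0.32))
    theta_wp: np.ndarray = field(default_factory=lambda: np.full(7, 0.12))
    theta_sat: np.ndarray = field(default_factory=lambda: np.full(7, 0.45))
    #: fraction of rainfall that infiltrates (the rest runs off; < 1 on
    #: sloping fields); irrigation is applied below the runoff-generating
    #: surface and infiltrates fully
    infiltration_frac: float = 1.0

    def __post_init__(self) -> None:
        for name in ("layer_depths", "theta_fc", "theta_wp", "theta_sat"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.layer_depths)
        if not (len(self.theta_fc) == len(self.theta_wp) == len(self.theta_sat) == n):
            raise ValueError("per-layer property lengths differ")
        if np.any(self.layer_depths <= 0):
            raise ValueError("layer depths must be positive")
        ok = (0 < self.theta_wp) & (self.theta_wp < self.theta_fc) & (
            self.theta_fc < self.theta_sat
        ) & (self.theta_sat < 1)
        if not np.all(ok):
            raise ValueError("require 0 < wp < fc < sat < 1 per layer")
        if not 0 < self.infiltration_frac <= 1:
            raise ValueError("infiltration_frac must be in (0, 1]")

    @property
    def n_layers(self) -> int:
        return len(self.layer_depths)

    @property
    def total_depth(self) -> float:
        return float(self.layer_depths.sum())


@dataclass(frozen=True)
class Management:
    sowing_date: dt.date
    irrigation_events: tuple = ()  # (date, depth mm)
    fertilization_events: tuple = ()  # carried but inert

    def irrigation_on(self, date: dt.date) -> float:
        return float(sum(d for when, d in self.irrigation_events if when == date))


@dataclass(frozen=True)
class CropParams:
    """Cultivar-level parameters of the surrogate.

    stage_gdd are cumulative GDD (base 0 °C) thresholds for green-up,
    jointing, heading-filling, milking and maturity; defaults are anchored to
    a warm-temperate continental climatology (October sowing, early-June
    maturity).
    """

    base_temp: float = 0.0  # °C
    stage_gdd: np.ndarray = field(
        default_factory=lambda: np.array([675.0, 895, 1120, 1495, 2030])
    )  # °C d
    lai_init: float = 0.3  # m2 m-2 established before winter
    lai_max: float = 7.0  # m2 m-2
    rgr: float = 0.09  # d-1 logistic relative growth rate
    senescence_rate: float = 0.07  # d-1 post-milking decline
    rue: float = 1.2  # g DM per MJ total shortwave
    harvest_index: float = 0.45
    #: fraction of harvest index lost under total grain-fill water stress
    #: (drought between milking and maturity shrivels kernels)
    hi_stress_sensitivity: float = 0.45
    k_ext: float = 0.6  # canopy light extinction
    et_coeff: float = 1.0  # multiplier on potential ET
    #: unsaturated vertical redistribution rate between adjacent layers,
    #: mm d-1 per unit moisture difference (capillary exchange; this is why
    #: a topsoil moisture reading carries root-zone information)
    soil_diffusivity: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage_gdd", np.asarray(self.stage_gdd, dtype=float))
        if len(self.stage_gdd) != 5 or np.any(np.diff(self.stage_gdd) <= 0):
            raise ValueError("stage_gdd must be 5 strictly increasing thresholds")
        if not 0 < self.harvest_index < 1:
            raise ValueError("harvest_index must be in (0,1)")
        if not 0 <= self.hi_stress_sensitivity < 1:
            raise ValueError("hi_stress_sensitivity must be in [0,1)")
        for name in ("lai_max", "rgr", "senescence_rate", "rue", "k_ext", "et_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CropState:
    day: int  # days after sowing
    lai: float
    theta: np.ndarray  # per-layer volumetric moisture, cm3 cm-3
    gdd: float = 0.0
    biomass: float = 0.0  # kg ha-1 above-ground dry matter
    stage: Stage = Stage.PRESOWING

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)


@dataclass
class Trajectory:
    """Daily states of one simulation plus the final yield (kg ha-1)."""

    dates: list
    lai: np.ndarray
    theta: np.ndarray  # (n_days, n_layers)
    gdd: np.ndarray
    biomass: np.ndarray
    stage: np.ndarray  # int codes
    stress: np.ndarray
    yield_: float
    soil: SoilProfile
    matured: bool = True
    fill_stress: float = 1.0  # mean stress over the grain-fill window

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "lai": self.lai,
                "theta_0_20": self.theta_topsoil(20.0),
                "gdd": self.gdd,
                "stage": [Stage(s).name.lower() for s in self.stage],
                "biomass": self.biomass,
                "stress": self.stress,
            }
        )

    def theta_topsoil(self, depth: float = 20.0) -> np.ndarray:
        """Thickness-weighted mean moisture of the top `depth` cm, per day."""
        w = _depth_weights(self.soil.layer_depths, depth)
        return self.theta @ w

    def stage_start(self, stage: Stage) -> dt.date | None:
        hit = np.nonzero(self.stage >= int(stage))[0]
        return self.dates[hit[0]] if hit.size else None

    def at(self, date: dt.date) -> pd.Series:
        i = self.dates.index(date)
        return self.to_dataframe().iloc[i]


# ---------------------------------------------------------------------------
# elementary pieces


def thermal_time(day: WeatherDay, base_temp: float = 0.0) -> float:
    """Daily growing degree days: mean temperature above the base, floored at 0."""
    return max(0.0, (day.tmax + day.tmin) / 2.0 - base_temp)


def water_stress_factor(theta_root, theta_wp, theta_fc):
    """Linear soil-water stress: 0 at/below wilting point, 1 at/above field capacity."""
    theta_root = np.asarray(theta_root, dtype=float)
    if np.any(np.asarray(theta_wp) >= np.asarray(theta_fc)):
        raise ValueError("degenerate profile: wilting point >= field capacity")
    f = (theta_root - theta_wp) / (theta_fc - theta_wp)
    return np.clip(f, 0.0, 1.0)


def potential_et(tmean: float, srad: float, alpha: float = 1.26) -> float:
    """Priestley–Taylor-style reference ET (mm d-1) from radiation and temperature.

    Net radiation is approximated as 77% of incoming shortwave; 0.408 converts
    MJ m-2 to mm of water; psychrometric constant 0.066 kPa/°C.
    """
    es_slope = 4098.0 * 0.6108 * np.exp(17.27 * tmean / (tmean + 237.3)) / (tmean + 237.3) ** 2
    pet = alpha * es_slope / (es_slope + 0.066) * 0.408 * 0.77 * srad
    return float(max(pet, 0.0))


def _depth_weights(layer_depths: np.ndarray, depth: float) -> np.ndarray:
    """Fraction of the [0, depth] window in each layer, normalised to sum 1."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    tops = np.concatenate([[0.0], np.cumsum(layer_depths)[:-1]])
    overlap = np.clip(np.minimum(tops + layer_depths, depth) - tops, 0.0, None)
    if overlap.sum() == 0:
        raise ValueError("depth above the profile top")
    return overlap / overlap.sum()


def effective_harvest_index(params: CropParams, fill_stress_mean) -> float:
    """Harvest index after grain-fill drought penalty.

    Full water supply during milking->maturity keeps the nominal index;
    total stress removes the hi_stress_sensitivity fraction, linearly.
    """
    return params.harvest_index * (
        1.0 - params.hi_stress_sensitivity * (1.0 - fill_stress_mean)
    )


def root_zone_theta(state: CropState, soil: SoilProfile, depth: float = 20.0) -> float:
    """Thickness-weighted mean soil moisture over [0, depth] cm."""
    if depth > soil.total_depth:
        raise ValueError("depth exceeds soil profile depth")
    return float(state.theta @ _depth_weights(soil.layer_depths, depth))


def _root_depth(gdd: np.ndarray, soil: SoilProfile) -> np.ndarray:
    """Rooting front (cm) deepening with thermal time, capped at the profile."""
    return np.minimum(np.maximum(10.0 + 0.12 * gdd, 10.0), soil.total_depth)


# ---------------------------------------------------------------------------
# the daily kernel


_layer_cache: dict = {}


def _layer_geom(soil: SoilProfile) -> tuple:
    """Cached (depths_mm, layer tops) for a SoilProfile instance."""
    key = id(soil)
    hit = _layer_cache.get(key)
    if hit is None:
        tops = np.concatenate([[0.0], np.cumsum(soil.layer_depths)[:-1]])
        hit = (soil.layer_depths * 10.0, tops)
        if len(_layer_cache) > 256:
            _layer_cache.clear()
        _layer_cache[key] = hit
    return hit


def advance_day(
    lai: np.ndarray,
    theta: np.ndarray,
    gdd: np.ndarray,
    biomass: np.ndarray,
    wx: WeatherDay,
    soil: SoilProfile,
    irrigation_mm: float,
    params: CropParams,
) -> dict:
    """Advance an ensemble of states by one day (vectorised over axis 0).

    Parameters are (n,) / (n, L) arrays; a single simulation uses n = 1.
    Returns a dict with the updated arrays plus diagnostics (stage, stress,
    infiltration, aet, drainage, all per member; fluxes in mm).
    """
    lai = np.array(lai, dtype=float, copy=True)
    theta = np.array(theta, dtype=float, copy=True)
    gdd = np.array(gdd, dtype=float, copy=True)
    biomass = np.array(biomass, dtype=float, copy=True)
    n, L = theta.shape
    depths_mm, tops = _layer_geom(soil)  # cm -> mm of column per unit theta

    # phenology
    gdd += thermal_time(wx, params.base_temp)
    stage = np.searchsorted(params.stage_gdd, gdd, side="right")  # 0..5

    # stress from current root-zone moisture
    rz = _root_depth(gdd, soil)
    frac = np.maximum(
        np.minimum(tops + soil.layer_depths, rz[:, None]) - tops, 0.0
    ) / soil.layer_depths  # (n, L) fraction of each layer inside the root zone
    w = frac * soil.layer_depths
    w /= w.sum(axis=1, keepdims=True)
    theta_rz = (theta * w).sum(axis=1)
    wp_rz = w @ soil.theta_wp
    fc_rz = w @ soil.theta_fc
    stress = np.minimum(np.maximum((theta_rz - wp_rz) / (fc_rz - wp_rz), 0.0), 1.0)

    # canopy: logistic growth green-up..heading-filling, senescence from milking
    growing = (stage >= 1) & (stage < 4)  # green-up .. heading-filling
    senescing = stage >= 4  # milking onward
    dlai = np.where(
        growing,
        params.rgr * stress * lai * (1.0 - lai / params.lai_max),
        0.0,
    )
    dlai = np.where(senescing, -params.senescence_rate * lai, dlai)
    lai = np.minimum(np.maximum(lai + dlai, 0.0), params.lai_max)

    # biomass by radiation-use efficiency (g m-2 -> kg ha-1 via factor 10)
    active = stage < 5  # pre-maturity
    fint = 1.0 - np.exp(-params.k_ext * lai)
    biomass += np.where(active, params.rue * wx.srad * fint * stress * 10.0, 0.0)

    # water balance: infiltration cascade to field capacity, then extraction
    storage0 = theta @ depths_mm
    infil = wx.precip * soil.infiltration_frac + irrigation_mm
    inflow = np.full(n, float(infil))
    for l in range(L):
        room = (soil.theta_fc[l] - theta[:, l]) * depths_mm[l]
        taken = np.minimum(np.maximum(room, 0.0), inflow)
        theta[:, l] += taken / depths_mm[l]
        inflow -= taken
    drainage = inflow  # excess below the profile

    # ET demand scales with canopy cover (bare-soil evaporation floor 0.25),
    # so canopy state and the water balance are two-way coupled
    tmean = (wx.tmax + wx.tmin) / 2.0
    kc = 0.25 + 0.75 * fint
    demand = params.et_coeff * stress * kc * potential_et(tmean, wx.srad)
    avail_rz = np.maximum(theta - soil.theta_wp, 0.0) * depths_mm * frac  # (n, L) mm
    total_avail = avail_rz.sum(axis=1)
    aet = np.minimum(demand, total_avail)
    share = avail_rz / np.maximum(total_avail, 1e-30)[:, None]
    theta -= aet[:, None] * share / depths_mm
    theta = np.minimum(np.maximum(theta, 0.0), soil.theta_sat)

    # unsaturated redistribution: capillary exchange between adjacent layers
    # relaxes moisture gradients (mass-conserving internal transfer)
    D = params.soil_diffusivity
    if D > 0:
        for l in range(L - 1):
            q = D * (theta[:, l + 1] - theta[:, l])  # mm d-1, >0 = upward
            theta[:, l] += q / depths_mm[l]
            theta[:, l + 1] -= q / depths_mm[l + 1]

    dstorage = theta @ depths_mm - storage0
    return {
        "lai": lai,
        "theta": theta,
        "gdd": gdd,
        "biomass": biomass,
        "stage": stage,
        "stress": stress,
        "infiltration": np.full(n, float(infil)),
        "aet": aet,
        "drainage": drainage,
        "dstorage": dstorage,
    }


def step(
    state: CropState,
    wx: WeatherDay,
    soil: SoilProfile,
    mgmt: Management,
    params: CropParams,
) -> CropState:
    """One-day update of a single crop state (thin wrapper over advance_day)."""
    out = advance_day(
        state.lai[None] if np.ndim(state.lai) else np.array([state.lai]),
        state.theta[None, :],
        np.array([state.gdd]),
        np.array([state.biomass]),
        wx,
        soil,
        mgmt.irrigation_on(wx.date),
        params,
    )
    return CropState(
        day=state.day + 1,
        lai=float(out["lai"][0]),
        theta=out["theta"][0],
        gdd=float(out["gdd"][0]),
        biomass=float(out["biomass"][0]),
        stage=Stage(int(out["stage"][0])),
    )


def simulate(
    soil: SoilProfile,
    wx: list[WeatherDay],
    mgmt: Management,
    params: CropParams,
    init_theta,
) -> Trajectory:
    """Run sowing -> maturity (or end of weather) and return the daily trajectory.

    Weather must cover consecutive days from the sowing date; a gap raises a
    ValueError naming the first missing date.  Deterministic in its inputs.
    """
    season = sorted((d for d in wx if d.date >= mgmt.sowing_date), key=lambda d: d.date)
    if not season or season[0].date != mgmt.sowing_date:
        raise ValueError(f"missing weather for date {mgmt.sowing_date}")
    init_theta = np.broadcast_to(np.asarray(init_theta, dtype=float), (soil.n_layers,)).copy()
    if np.any(init_theta < 0) or np.any(init_theta > soil.theta_sat):
        raise ValueError("initial theta outside [0, theta_sat]")

    lai = np.array([params.lai_init])
    theta = init_theta[None, :].copy()
    gdd = np.zeros(1)
    biomass = np.zeros(1)

    dates, lai_h, theta_h, gdd_h, bm_h, st_h, str_h = [], [], [], [], [], [], []
    expected = mgmt.sowing_date
    matured = False
    fill_sum = 0.0
    fill_days = 0
    for day in season:
        if day.date != expected:
            raise ValueError(f"missing weather for date {expected}")
        expected = expected + dt.timedelta(days=1)
        out = advance_day(
            lai, theta, gdd, biomass, day, soil, mgmt.irrigation_on(day.date), params
        )
        lai, theta, gdd, biomass = out["lai"], out["theta"], out["gdd"], out["biomass"]
        dates.append(day.date)
        lai_h.append(lai[0])
        theta_h.append(theta[0].copy())
        gdd_h.append(gdd[0])
        bm_h.append(biomass[0])
        st_h.append(int(out["stage"][0]))
        str_h.append(out["stress"][0])
        if out["stage"][0] == Stage.MILKING:
            fill_sum += out["stress"][0]
            fill_days += 1
        if out["stage"][0] >= Stage.MATURE:
            matured = True
            break

    fill_stress = fill_sum / fill_days if fill_days else 1.0
    return Trajectory(
        dates=dates,
        lai=np.array(lai_h),
        theta=np.array(theta_h),
        gdd=np.array(gdd_h),
        biomass=np.array(bm_h),
        stage=np.array(st_h),
        stress=np.array(str_h),
        yield_=float(effective_harvest_index(params, fill_stress) * biomass[0]),
        soil=soil,
        matured=matured,
        fill_stress=float(fill_stress),
    )


def weather_from_frame(df: pd.DataFrame) -> list[WeatherDay]:
    """Build the daily forcing list from a date,tmax,tmin,precip,srad table."""
    need = {"date", "tmax", "tmin", "precip", "srad"}
    if not need.issubset(df.columns):
        raise ValueError(f"weather table must have columns {sorted(need)}")
    out = []
    for row in df.itertuples(index=False):
        date = row.date
        if isinstance(date, str):
            date = dt.date.fromisoformat(date)
        elif isinstance(date, pd.Timestamp):
            date = date.date()
        out.append(
            WeatherDay(date, float(row.tmax), float(row.tmin), float(row.precip), float(row.srad))
        )
    return out
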