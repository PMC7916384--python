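"""End-to-end orchestration: classify -> retrieve -> assimilate -> yield.

The pipeline runs on a synthetic scenario (twin-experiment protocol): scenes
are rendered from known truth trajectories, LAI and soil moisture are
retrieved per scene, assimilated per site under one or more strategies, the
stage-weighted composites are regressed on measured yields per water regime,
and validation metrics plus a strategy comparison are produced.  A regional
yield map is built by bridging scene-scale retrievals to the assimilated
site values with per-stage linear regressions.

All randomness flows from the seeds in the run configuration.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import retrieval as rt
from .area_classification import class_areas, regime_split, wheat_mask
from .assimilation import (
    AssimilationConfig,
    AssimilationResults,
    CropAssimilationModel,
    Observation,
    make_observation,
)
from .rasters import Raster
from .synthetic_data import (
    NOMINAL_INIT_THETA,
    NOMINAL_PARAMS,
    NOMINAL_SOIL,
    Scenario,
    ScenarioConfig,
    weather_to_frame,
)
from .yield_mapping import (
    LAI_STAGE_WEIGHTS,
    SM_STAGE_WEIGHTS,
    StageWeightedYieldModel,
    ValidationReport,
    YIELD_STAGES,
    compare_strategies,
    fit_yield_model,
    predict_yield,
    stage_composite,
    validate,
)

logger = logging.getLogger(__name__)

STRATEGIES = ("LAI_only", "SM_only", "joint")


@dataclass(frozen=True)
class RunConfig:
    scenario: ScenarioConfig = ScenarioConfig()
    assimilation: AssimilationConfig = AssimilationConfig()
    strategies: tuple = STRATEGIES
    ndvi_threshold: float = 0.25
    elev_thresh: float = 600.0
    slope_thresh: float = 15.0
    #: last scene date fed to the filter (later scenes serve classification only)
    assimilation_end: dt.date = dt.date(2019, 5, 24)
    output_dir: str = "wheatda_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {
            "scenario", "assimilation", "strategies", "ndvi_threshold",
            "elev_thresh", "slope_thresh", "assimilation_end", "output_dir",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        if "scenario" in raw:
            sc = dict(raw["scenario"])
            bad = set(sc) - set(ScenarioConfig.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown scenario keys: {sorted(bad)}")
            for key in ("season_start", "season_end", "sowing_date"):
                if key in sc and isinstance(sc[key], str):
                    sc[key] = dt.date.fromisoformat(sc[key])
            kw["scenario"] = ScenarioConfig(**sc)
        if "assimilation" in raw:
            ac = dict(raw["assimilation"])
            bad = set(ac) - set(AssimilationConfig.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown assimilation keys: {sorted(bad)}")
            kw["assimilation"] = AssimilationConfig(**ac)
        if "strategies" in raw:
            bad = set(raw["strategies"]) - set(STRATEGIES)
            if bad:
                raise ValueError(f"unknown strategies: {sorted(bad)}")
            kw["strategies"] = tuple(raw["strategies"])
        for key in ("ndvi_threshold", "elev_thresh", "slope_thresh", "output_dir"):
            if key in raw:
                kw[key] = raw[key]
        if "assimilation_end" in raw:
            v = raw["assimilation_end"]
            kw["assimilation_end"] = dt.date.fromisoformat(v) if isinstance(v, str) else v
        return cls(**kw)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict  # path -> sha256
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class Retrievals:
    """Per-date retrieved rasters plus the NDVI stack used for classification."""

    lai: dict  # date -> Raster
    sm: dict  # date -> Raster
    ndvi: dict  # date -> Raster


def retrieve_scenes(scenario: Scenario, rng: np.random.Generator) -> Retrievals:
    """Render scenes and run the retrieval chain on every acquisition date.

    Soil-moisture inversion uses the plant water content from the same-date
    optical rendering (the operational near-coincident acquisition), the
    water cloud model inversion in linear power, then the dB-scale linear
    moisture regression.
    """
    cfg = scenario.cfg
    lai_model = rt.lai_model_from_coefficients()
    sm_model = rt.sm_model_from_coefficients()
    lai_rasters, ndvi_rasters, sm_rasters = {}, {}, {}
    for date in sorted(set(cfg.s2_dates)):
        scene = scenario.render_optical(date, rng)
        nd = rt.ndvi(scene.red.data, scene.nir.data)
        ndvi_rasters[date] = scene.red.like(nd)
        lai_rasters[date] = scene.red.like(rt.apply_retrieval(lai_model, nd))
    for date in sorted(set(cfg.s1_dates)):
        sar = scenario.render_sar(date, rng)
        optical = scenario.render_optical(date, rng)
        m_veg = rt.mveg_from_ndwi(rt.ndwi(optical.nir.data, optical.mir.data))
        sigma_soil = rt.wcm_invert(
            rt.db_to_linear(sar.sigma_can_db.data), m_veg, sar.incidence_deg
        )
        with np.errstate(invalid="ignore"):
            sm = rt.apply_retrieval(sm_model, 10.0 * np.log10(np.where(sigma_soil > 0, sigma_soil, np.nan)))
        sm_rasters[date] = sar.sigma_can_db.like(sm)
    return Retrievals(lai=lai_rasters, sm=sm_rasters, ndvi=ndvi_rasters)


def site_mean(raster: Raster, scenario: Scenario, k: int) -> float:
    rows, cols = scenario.site_pixels(k)
    return float(np.nanmean(raster.data[rows, cols]))


def build_observations(
    scenario: Scenario,
    retr: Retrievals,
    assim_cfg: AssimilationConfig,
    end_date: dt.date,
) -> dict:
    """Per-site observation sequences from the retrieved rasters."""
    obs_by_site: dict[str, list[Observation]] = {t.site_id: [] for t in scenario.truths}
    for date, raster in retr.lai.items():
        if date > end_date:
            continue
        for k, t in enumerate(scenario.truths):
            v = site_mean(raster, scenario, k)
            if np.isfinite(v):
                obs_by_site[t.site_id].append(make_observation(date, "LAI", v, assim_cfg))
    for date, raster in retr.sm.items():
        if date > end_date:
            continue
        for k, t in enumerate(scenario.truths):
            v = site_mean(raster, scenario, k)
            if np.isfinite(v):
                obs_by_site[t.site_id].append(make_observation(date, "SM", v, assim_cfg))
    return obs_by_site


def assimilate_sites(
    scenario: Scenario,
    obs_by_site: dict,
    assim_cfg: AssimilationConfig,
    strategies=STRATEGIES,
) -> dict:
    """Run the EnKF per site and strategy with the nominal (imperfect) model.

    Returns {(site_id, strategy): AssimilationResults}.  The assimilating
    model shares each site's management (sowing, irrigation) but uses the
    nominal cultivar parameters, soil and initial moisture — the realistic
    situation where the simulator is calibrated regionally, not per field.
    """
    from .crop_model import simulate

    out = {}
    for k, t in enumerate(scenario.truths):
        open_loop = simulate(
            NOMINAL_SOIL, scenario.weather, t.management, NOMINAL_PARAMS, NOMINAL_INIT_THETA
        )
        for j, strategy in enumerate(strategies):
            cfg = replace(
                assim_cfg, strategy=strategy, seed=(assim_cfg.seed + 97 * k + j) % (2**31 - 1)
            )
            model = CropAssimilationModel(
                obs_by_site[t.site_id],
                scenario.weather,
                NOMINAL_SOIL,
                t.management,
                NOMINAL_PARAMS,
                NOMINAL_INIT_THETA,
                cfg,
            )
            out[(t.site_id, strategy)] = model.fit(open_loop=open_loop)
    return out


def site_composites(scenario: Scenario, results: dict, strategies=STRATEGIES) -> pd.DataFrame:
    """Stage-weighted LAI and SM composites of the assimilated trajectories."""
    cfg = scenario.cfg
    rows = []
    for t in scenario.truths:
        for strategy in strategies:
            res = results[(t.site_id, strategy)]
            lai_vals = {s: res.value_at(d, "lai") for s, d in cfg.stage_dates_lai.items()}
            sm_vals = {s: res.value_at(d, "sm") for s, d in cfg.stage_dates_sm.items()}
            rows.append(
                {
                    "site_id": t.site_id,
                    "regime": t.regime,
                    "role": scenario.roles[t.site_id],
                    "strategy": strategy,
                    "lai_composite": stage_composite(lai_vals, LAI_STAGE_WEIGHTS),
                    "sm_composite": stage_composite(sm_vals, SM_STAGE_WEIGHTS),
                }
            )
    return pd.DataFrame(rows)


def fit_and_validate(
    composites: pd.DataFrame, samples: pd.DataFrame, strategies=STRATEGIES
) -> tuple[dict, list, pd.DataFrame]:
    """Per-regime, per-strategy yield models on calibration sites, validated
    on the held-out sites.  Returns (models, reports, comparison table)."""
    data = composites.merge(samples[["site_id", "yield"]], on="site_id")
    models, reports = {}, []
    for regime in ("irrigated", "rain_fed"):
        for strategy in strategies:
            sub = data[(data.regime == regime) & (data.strategy == strategy)]
            cal = sub[sub.role == "cal"]
            val = sub[sub.role == "val"]
            res = StageWeightedYieldModel(
                cal.drop(columns=["site_id", "regime", "role", "strategy"]),
                regime,
                strategy,
            ).fit()
            models[(regime, strategy)] = res
            pred = res.predict(val)
            reports.append(validate(pred, val["yield"].to_numpy(), regime, strategy))
    comparison = compare_strategies(reports)
    return models, reports, comparison


def regional_yield_map(
    scenario: Scenario,
    retr: Retrievals,
    results: dict,
    models: dict,
    comparison: pd.DataFrame,
    run_cfg: RunConfig,
):
    """Classify the scene stack and map yield with each regime's winning model.

    Scene-scale composites are built by regressing, per stage, the retrieved
    site values onto the assimilated ones over the calibration sites and
    applying that bridge to the full retrieved raster.
    """
    cfg = scenario.cfg
    nd = retr.ndvi
    mask = wheat_mask(
        nd[dt.date(2019, 3, 17)], nd[dt.date(2019, 4, 16)], nd[dt.date(2019, 6, 10)],
        threshold=run_cfg.ndvi_threshold,
    ) if dt.date(2019, 3, 17) in nd else None
    if mask is None:
        raise ValueError("classification scene dates missing from the scenario")
    regime_mask = regime_split(
        mask, scenario.terrain, run_cfg.elev_thresh, run_cfg.slope_thresh
    )
    areas = class_areas(regime_mask)

    winners = {
        row.regime: row.strategy
        for row in comparison[comparison.recommended].itertuples(index=False)
    }
    cal_ids = [t.site_id for t in scenario.truths if scenario.roles[t.site_id] == "cal"]

    def bridged_composite(var: str, strategy: str) -> Raster:
        stage_dates = cfg.stage_dates_lai if var == "lai" else cfg.stage_dates_sm
        rasters = retr.lai if var == "lai" else retr.sm
        weights = LAI_STAGE_WEIGHTS if var == "lai" else SM_STAGE_WEIGHTS
        stacked = {}
        for stage, date in stage_dates.items():
            raster = rasters[date]
            x = []
            y = []
            for k, t in enumerate(scenario.truths):
                if t.site_id not in cal_ids:
                    continue
                x.append(site_mean(raster, scenario, k))
                y.append(results[(t.site_id, strategy)].value_at(date, var))
            bridge = rt.fit_linear_retrieval(x, y, "LAI" if var == "lai" else "SM", date)
            stacked[stage] = rt.apply_retrieval(bridge, raster.data)
        comp = np.stack([stacked[s] for s in YIELD_STAGES], axis=-1) @ weights.as_array()
        return raster.like(comp)

    composite_rasters = {}
    for regime, strategy in winners.items():
        need = {"LAI_only": ["lai"], "SM_only": ["sm"], "joint": ["lai", "sm"]}[strategy]
        for var in need:
            composite_rasters.setdefault((var, strategy), bridged_composite(var, strategy))

    # assemble per-regime predictions on one map
    yield_map = Raster(np.full(cfg.grid_shape, np.nan), cfg.pixel_size)
    for code, regime in ((1, "irrigated"), (2, "rain_fed")):
        strategy = winners[regime]
        lai_c = composite_rasters.get(("lai", strategy))
        sm_c = composite_rasters.get(("sm", strategy))
        part = predict_yield(
            {regime: models[(regime, strategy)]}, regime_mask.codes, lai_c, sm_c
        )
        sel = regime_mask.codes.data == code
        yield_map.data[sel] = part.data[sel]
    return regime_mask, areas, yield_map, winners


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(run_cfg: RunConfig) -> RunManifest:
    """Execute the full analysis and write all artifacts to output_dir."""
    from pathlib import Path

    t0 = time.time()
    out_dir = Path(run_cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    scenario = Scenario(run_cfg.scenario)
    logger.info("scenario generated (%.1fs)", time.time() - t0)
    rng = np.random.default_rng((run_cfg.scenario.seed + 1000) % (2**31 - 1))
    retr = retrieve_scenes(scenario, rng)
    logger.info("retrieval done (%.1fs)", time.time() - t0)
    obs = build_observations(scenario, retr, run_cfg.assimilation, run_cfg.assimilation_end)
    results = assimilate_sites(scenario, obs, run_cfg.assimilation, run_cfg.strategies)
    logger.info("assimilation done (%.1fs)", time.time() - t0)
    samples = scenario.sample_field_measurements()
    composites = site_composites(scenario, results, run_cfg.strategies)
    models, reports, comparison = fit_and_validate(composites, samples, run_cfg.strategies)
    regime_mask, areas, yield_map, winners = regional_yield_map(
        scenario, retr, results, models, comparison, run_cfg
    )
    logger.info("yield mapping done (%.1fs)", time.time() - t0)

    weather_to_frame(scenario.weather).to_csv(out_dir / "weather.csv", index=False)
    samples.to_csv(out_dir / "sites.csv", index=False)
    pd.DataFrame(
        [
            {"site_id": sid, "date": o.date.isoformat(), "kind": o.kind,
             "value": o.value, "sd": o.sd}
            for sid, seq in obs.items()
            for o in seq
        ]
    ).to_csv(out_dir / "observations.csv", index=False)
    diag = []
    winners_by_regime = {
        row.regime: row.strategy
        for row in comparison[comparison.recommended].itertuples(index=False)
    }
    for t in scenario.truths:
        strategy = winners_by_regime[t.regime]
        res = results[(t.site_id, strategy)]
        ol = res.open_loop_series("lai")
        d = res.trajectory.assign(site_id=t.site_id, strategy=strategy)
        d["lai_open_loop"] = d["date"].map(ol).astype(float)
        diag.append(d)
    pd.concat(diag, ignore_index=True).to_csv(
        out_dir / "assimilation_diagnostics.csv", index=False
    )
    rt.model_to_yaml(rt.lai_model_from_coefficients(), out_dir / "lai_retrieval_model.yaml")
    rt.model_to_yaml(rt.sm_model_from_coefficients(), out_dir / "sm_retrieval_model.yaml")
    composites.to_csv(out_dir / "composites.csv", index=False)
    areas.to_csv(out_dir / "class_areas.csv", index=False)
    comparison.to_csv(out_dir / "strategy_comparison.csv", index=False)
    regime_mask.codes.write_ascii(out_dir / "regime_mask.asc")
    yield_map.write_ascii(out_dir / "yield_map.asc")
    with open(out_dir / "yield_models.txt", "w") as fh:
        for (regime, strategy), res in models.items():
            fh.write(res.summary() + "\n\n")
        fh.write("recommended strategy per regime: " + json.dumps(winners) + "\n")

    cfg_yaml = yaml.safe_dump(
        json.loads(json.dumps(asdict(run_cfg), default=str)), sort_keys=True
    )
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        seed=run_cfg.scenario.seed,
        version=_version(),
        outputs=outputs,
        timestamp=dt.datetime.now().isoformat(timespec="seconds"),
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline complete (%.1fs)", time.time() - t0)
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("wheatda")
    except Exception:
        return "unknown"


# ---------------------------------------------------------------------------
# twin-experiment harness


def twin_replicate(
    scenario_cfg: ScenarioConfig,
    assim_cfg: AssimilationConfig,
    strategies=STRATEGIES,
    assimilation_end: dt.date = dt.date(2019, 5, 24),
) -> dict:
    """One replicate: state RMSEs vs truth and per-regime yield validation."""
    scenario = Scenario(scenario_cfg)
    rng = np.random.default_rng((scenario_cfg.seed + 1000) % (2**31 - 1))
    retr = retrieve_scenes(scenario, rng)
    obs = build_observations(scenario, retr, assim_cfg, assimilation_end)
    results = assimilate_sites(scenario, obs, assim_cfg, strategies)
    samples = scenario.sample_field_measurements()
    composites = site_composites(scenario, results, strategies)
    _, reports, comparison = fit_and_validate(composites, samples, strategies)

    rec: dict = {"seed": scenario_cfg.seed}
    # state-estimation skill: LAI via the LAI_only run, SM via SM_only,
    # falling back to joint when a single-variable strategy was not run
    lai_strat = "LAI_only" if "LAI_only" in strategies else "joint"
    sm_strat = "SM_only" if "SM_only" in strategies else "joint"
    for var, strat, key in (("lai", lai_strat, "lai"), ("sm", sm_strat, "sm")):
        a, o = [], []
        for t in scenario.truths:
            res = results[(t.site_id, strat)]
            truth = t.series(var)
            a.append(res.rmse_vs(truth, var))
            o.append(res.open_loop_rmse_vs(truth, var))
        rec[f"rmse_{key}_assim"] = float(np.mean(a))
        rec[f"rmse_{key}_open"] = float(np.mean(o))
    for r in reports:
        rec[f"yield_rmse_{r.regime}_{r.strategy}"] = r.rmse
        rec[f"yield_are_{r.regime}_{r.strategy}"] = r.are
    for row in comparison[comparison.recommended].itertuples(index=False):
        rec[f"winner_{row.regime}"] = row.strategy
    return rec


def twin_experiment(
    scenario_cfg: ScenarioConfig = ScenarioConfig(),
    assim_cfg: AssimilationConfig = AssimilationConfig(),
    n_replicates: int = 20,
    base_seed: int = 0,
    strategies=STRATEGIES,
) -> pd.DataFrame:
    """Seeded replicates of the full twin experiment; one row per replicate."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for i in range(n_replicates):
        cfg_i = replace(scenario_cfg, seed=(base_seed + 1009 * i) % (2**31 - 1))
        rows.append(twin_replicate(cfg_i, assim_cfg, strategies))
        logger.info("replicate %d/%d done", i + 1, n_replicates)
    return pd.DataFrame(rows)


def summarize_twin(table: pd.DataFrame) -> pd.DataFrame:
    """Medians and IQRs of the replicate table's numeric columns."""
    num = table.select_dtypes("number").drop(columns=["seed"], errors="ignore")
    q = num.quantile([0.25, 0.5, 0.75])
    out = pd.DataFrame(
        {"median": q.loc[0.5], "iqr": q.loc[0.75] - q.loc[0.25]}
    )
    if len(table) == 1:
        out["iqr"] = np.nan
    return out
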