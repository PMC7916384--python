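# wheatda

Winter-wheat yield estimation for arid and semi-arid regions by
**ensemble Kalman filter (EnKF) assimilation** of satellite-retrieved leaf
area index (LAI) and surface soil moisture into a daily crop growth model,
with **stage-weighted yield regression** applied separately to irrigated
and rain-fed growing areas.

The package is for agro-ecosystem modellers and remote-sensing scientists
who want a compact, fully testable implementation of the
retrieval → assimilation → yield-mapping chain, including a synthetic-data
generator that supports end-to-end *twin experiments* (known truth, rendered
scenes, scored estimates) without any downloads.

## The method

**Retrievals.** LAI comes from an empirical NDVI regression,
`LAI = 8.8049·NDVI − 0.9866`.  Soil moisture comes from SAR backscatter via
the water cloud model, which splits canopy backscatter into direct
vegetation scattering and soil scattering attenuated twice by the canopy:

    σ⁰_can(θ) = σ⁰_veg(θ) + γ²(θ)·σ⁰_soil(θ)
    σ⁰_veg(θ) = A·m_veg·cosθ·(1 − γ²(θ)),   γ²(θ) = exp(−2·B·m_veg·secθ)

with wheat coefficients A = 0.0018, B = 0.138 and plant water content
`m_veg = 1.44·NDWI² + 1.36·NDWI + 0.34` (kg m⁻²).  The inverted soil
backscatter (dB) maps to volumetric moisture through
`θ_v = 0.0133·σ⁰_soil + 0.3815`.

**Assimilation.**  The crop model is a reduced-order daily winter-wheat
simulator (GDD phenology, logistic canopy, layered cascading-bucket water
balance, radiation-use-efficiency biomass) carrying the state vector
`[LAI, θ₁…θ₇]`.  At each scene date the stochastic EnKF update

    Aᵃ_k = Aᶠ_k + P_k Hᵀ (H P_k Hᵀ + R_k)⁻¹ (D_k − H Aᶠ_k)

is applied with multiplicative model-error SDs of 17% (LAI) and 9% (soil
moisture) and observation SDs of 13% and 8%.  Three strategies are
compared: assimilate LAI only, soil moisture only, or both jointly (one
stacked observation vector, so cross-covariances couple the corrections).

**Yield.**  Assimilated LAI and 0–20 cm moisture are composited over the
green-up, jointing, heading-filling and milking stages with fixed weights
(LAI: 0.0550/0.2650/0.5660/0.1140; moisture: 0.0555/0.5655/0.2605/0.1185)
and regressed on measured yields per regime — terrain-classified irrigated
(< 600 m, < 15° slope) versus rain-fed wheat.  Validation reports RMSE
(kg ha⁻¹) and ARE (mean absolute relative error, %).

See `docs/methods.md` for model equations, defaults and limitations.

## Worked example

Generate a 45-site scenario (25 irrigated, 20 rain-fed), retrieve, run all
three assimilation strategies, and compare yield models:

```python
import datetime as dt
import numpy as np
from wheatda import Scenario, ScenarioConfig
from wheatda.assimilation import AssimilationConfig
from wheatda.pipeline import (retrieve_scenes, build_observations,
                              assimilate_sites, site_composites, fit_and_validate)

scenario = Scenario(ScenarioConfig(seed=0))
retr = retrieve_scenes(scenario, np.random.default_rng(1000))
assim = AssimilationConfig(seed=0)
obs = build_observations(scenario, retr, assim, dt.date(2019, 5, 24))
results = assimilate_sites(scenario, obs, assim)

print(results[("S00", "joint")].summary())
composites = site_composites(scenario, results)
models, reports, comparison = fit_and_validate(
    composites, scenario.sample_field_measurements())
print(comparison[["regime", "strategy", "rmse", "are", "rank", "recommended"]]
      .round(2).to_string(index=False))
```

Output:

```
Crop data assimilation (ensemble Kalman filter)
================================================
strategy:          joint
ensemble size:     100
model error SDs:   LAI 17%, SM 9%
obs error SDs:     LAI 13%, SM 8%
updates applied:   12
assimilated yield: 4127.9 +/- 516.8 kg ha-1
open-loop yield:   4691.5 kg ha-1

   regime strategy    rmse   are  rank  recommended
irrigated LAI_only  665.96  7.46     1         True
irrigated    joint  713.56  8.52     2        False
irrigated  SM_only 1552.14 18.63     3        False
 rain_fed    joint  639.80 16.71     1         True
 rain_fed LAI_only  669.99 15.54     2        False
 rain_fed  SM_only  736.22 18.37     3        False
```

Reading this: for rain-fed site S00 the filter applied 12 scene updates and
pulled the yield estimate from the open-loop 4692 down to 4128 kg ha⁻¹
(ensemble SD 517).  In the strategy comparison, assimilating **LAI alone**
validates best in irrigated areas (RMSE 666 kg ha⁻¹, ARE 7.5%), while the
**joint** LAI + soil-moisture strategy wins in water-stressed rain-fed
areas (RMSE 640 kg ha⁻¹) — canopy information suffices when water is not
limiting, but under stress the moisture state carries yield information the
canopy cannot see.

The same chain is available from the shell:

```bash
wheatda run-all --seed 0 --out run0        # full pipeline + yield map
wheatda twin --replicates 20 --seed 42     # replicated twin experiment
```

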