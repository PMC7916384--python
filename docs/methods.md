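# Methods

`wheatda` estimates winter-wheat yield by assimilating remotely sensed leaf
area index (LAI) and surface soil moisture into a daily crop growth model
with an ensemble Kalman filter (EnKF), then regressing stage-weighted
composites of the assimilated states on measured yields, separately for
irrigated and rain-fed growing areas.  This note documents the model, the
numerical choices, and what the synthetic twin experiments do and do not
demonstrate.

## The crop growth surrogate

The simulator is a deliberately reduced-order stand-in for a full
CERES-Wheat/DSSAT-class model.  It carries exactly the states a
remote-sensing assimilation system can observe — LAI and layered volumetric
soil moisture — plus thermal time, biomass and yield.  No numeric
equivalence with CERES-Wheat is claimed; nitrogen and carbon dynamics are
out of scope because only LAI and water states are assimilated.

**Phenology.** Growing degree days (GDD) accumulate as
`max(0, (tmax+tmin)/2 − T_base)` with `T_base = 0 °C`.  Five stages —
green-up, jointing, heading-filling, milking, maturity — trigger at fixed
cumulative GDD thresholds.  The nominal thresholds (600, 895, 1120, 1495,
2030 °C·d) are anchored to the package's default warm-temperate
climatology so that an October-10 sowing reaches green-up in late February,
jointing on about April 1, heading-filling in mid-April, milking in
mid-May and maturity in early June, with the seasonal LAI peak about 200
days after sowing.

**Canopy.** LAI starts at `lai_init` (0.3 by default; 0.6 in the synthetic
scenario, a well-tillered stand) and is constant until green-up — an
explicit overwinter-dormancy gate; without it an autumn sowing would
saturate the logistic in midwinter.  From green-up to the milking stage it
grows logistically, `dLAI = rgr · stress · LAI · (1 − LAI/LAI_max)`, and
from milking it declines exponentially at `senescence_rate`.

**Water balance.** Seven soil layers (0–10, 10–20, 20–50, 50–80, 80–120,
120–160, 160–200 cm) form a cascading bucket: infiltrating water fills
each layer to field capacity and the surplus drains downward; drainage
below the profile leaves the system.  A fraction `1 − infiltration_frac`
of rainfall is lost to surface runoff (a soil/terrain property; sloping
rain-fed fields lose up to ~45%, irrigation infiltrates fully).  After
extraction, adjacent layers exchange water by a linear unsaturated
redistribution flux (`soil_diffusivity`, default 30 mm d⁻¹ per unit
moisture difference), a mass-conserving relaxation of vertical gradients.
This capillary exchange is what makes a 0–20 cm moisture observation
informative about root-zone storage — the physical basis for assimilating
a surface reading into a 2 m profile.  Potential ET is a Priestley–Taylor
style radiation formula (net radiation ≈ 0.77 of incoming shortwave,
α = 1.26), chosen because wind and humidity forcings are not part of the
weather contract.  Actual ET is potential ET × a linear water-stress factor
(0 at wilting point, 1 at field capacity, computed over the root zone,
whose depth deepens with thermal time at 0.12 cm per °C·d from 10 cm to the
profile bottom) × a canopy crop coefficient `0.25 + 0.75·(1 − exp(−k·LAI))`.
The crop coefficient makes canopy state and the water budget two-way
coupled: a bigger canopy transpires more.  This coupling is what
distinguishes the assimilation strategies — correcting LAI alone changes
future water demand without correcting the moisture state itself.
Extraction is partitioned over root-zone layers in proportion to thickness
× plant-available water, and each day's budget closes to better than
1e-9 mm by construction (asserted in tests).

**Biomass and yield.** `Δbiomass = RUE · S↓ · (1 − exp(−k·LAI)) · stress ·
10` kg ha⁻¹ d⁻¹ with extinction `k = 0.6` and radiation-use efficiency RUE
in g per MJ of total shortwave.  Yield is `HI_eff × biomass` at maturity,
where the effective harvest index carries a grain-fill drought penalty:
`HI_eff = HI · (1 − s_HI · (1 − stress̄_fill))` with nominal `HI = 0.45`,
sensitivity `s_HI = 0.45`, and `stress̄_fill` the mean stress over the
milking→maturity window.  Drought during grain fill shrivels kernels and
cuts the harvest index even when the canopy was built earlier — a yield
pathway the LAI trajectory cannot see but the moisture state can.

All daily updates are vectorised over a member axis, so the EnKF propagates
its whole ensemble through one kernel call per day.

## Retrieval operators

* NDVI and NDWI from red/NIR and NIR/MIR reflectance; denominators below
  1e-12 become nodata, and nodata propagates through every operator.
* Plant water content `m_veg = 1.44·NDWI² + 1.36·NDWI + 0.34` (kg m⁻²),
  clamped at ≥ 0.
* Water cloud model (WCM): `σ⁰_can = σ⁰_veg + γ²·σ⁰_soil` with
  `σ⁰_veg = A·m_veg·cos θ·(1 − γ²)` and `γ² = exp(−2·B·m_veg/cos θ)`,
  wheat coefficients A = 0.0018, B = 0.138.  The model operates in linear
  power; scenes carry dB, with explicit conversions.  The inversion is the
  exact algebraic inverse wherever `γ² > 1e-3`; denser canopies are masked
  rather than extrapolated.
* Empirical linear retrievals: `LAI = 8.8049·NDVI − 0.9866` and
  `θ = 0.0133·σ⁰_soil(dB) + 0.3815`.  The moisture regression is applied on
  the dB scale, where its coefficients produce physically plausible values
  for typical negative-dB agricultural soils.  Retrievals are clamped to
  physical ranges (LAI ≥ 0; θ ∈ [0, 0.6] cm³ cm⁻³) because linear models
  extrapolate.  A fixed 39° incidence (mid-swath typical) is the synthetic
  default.

## Ensemble Kalman filter

State vector per member: `[LAI, θ₁…θ₇]`.  Members are propagated
continuously through the crop model.  At each observation date a
multiplicative model-error perturbation is applied to form the forecast
set — relative SDs 17% (LAI) and 9% (soil moisture) — and the stochastic
(perturbed-observation) update is computed with observation SDs of 13%
(retrieved LAI) and 8% (retrieved moisture) times the observed value,
floored at 0.01 in state units to avoid zero-variance observations.  The
forecast covariance is the ensemble sample covariance; the LAI observation
operator selects the first state component and the moisture operator is the
thickness-weighted 0–20 cm aggregate (matching how field moisture is
measured), so cross-covariances update deeper layers and, in the joint
strategy, couple the LAI and moisture corrections.  A deterministic
unperturbed-observation variant exists for unit testing; singular
innovation covariances are regularised by inflating the R diagonal.
Analysis members are clamped to physical bounds (clamp-after-update, not
rejection).  Default ensemble size is 100 — large enough that sampling
error is well below the prescribed error SDs for an 8-dimensional state,
small enough for desk-scale replication.  The filter converges to the
exact Kalman solution on a linear Gaussian system (oracle test at 5000
members, 3 Monte Carlo SEs).

Three strategies: `LAI_only`, `SM_only`, and `joint` (one stacked
observation vector, shared cross-covariances).  Yield is reported both as
each member's own integration (mean ± SD) and, for the mapping, through
the stage-composite regressions below.

## Stage-weighted yield models

Assimilated LAI is sampled on the scene dates standing for green-up,
jointing, heading-filling and milking (17 Mar, 1 Apr, 16 Apr, 21 May);
assimilated 0–20 cm moisture on 2 Mar, 7 Apr, 19 Apr, 13 May.  Composites
use fixed weights — LAI: 0.0550, 0.2650, 0.5660, 0.1140; moisture: 0.0555,
0.5655, 0.2605, 0.1185 — taken as configuration (their analytic-hierarchy
derivation is out of scope); both sets must sum to 1 and are validated at
load.  Per regime and strategy, ordinary least squares relates the
composites (one predictor for single-variable strategies, both for joint)
to measured yield on the calibration sites (10 per regime); the held-out
sites (15 irrigated, 10 rain-fed) give RMSE and ARE.  ARE is defined here
as the **mean absolute relative error** across validation sites, in
percent — alternatives (e.g. relative error of totals) exist and would give
different numbers.  Strategies are ranked by RMSE, ties broken by ARE and
then by declaration order (flagged).

Regional maps bridge scene-scale retrievals to assimilated values with a
per-stage OLS fit across calibration sites (the functional form of this
field-to-region step was an open design choice), composite the bridged
rasters, and apply each regime's winning model per pixel.

## Area classification

Wheat pixels satisfy NDVI(mid-March) > 0.25 AND NDVI(mid-April) > 0.25 AND
NDVI(June) < 0.25 AND NDVI(April) > NDVI(June).  Wheat pixels below 600 m
elevation with slope below 15° are irrigated; **all remaining wheat pixels
are rain-fed** (complement rule).  The literal rain-fed definition
(elevation > 600 m and slope > 15°) would leave combinations such as
(500 m, 20°) unlabelled, so the complement is used and documented.  Slope
can be derived from a DEM by central finite differences when not supplied.

## The synthetic scenario and what the twin experiments show

The generator emulates a semi-arid warm-temperate winter-wheat season:
sinusoidal temperature (mean 13 °C, amplitude 12 °C, coldest mid-January)
and radiation, Poisson-gamma rainfall averaging ≈300 mm over the October–
June season (the in-season share of a 450–600 mm annual climate), a 12-day
SAR cadence and an irregular cloud-screened optical cadence, 45 sites (25
irrigated, 20 rain-fed) tiled as rectangular fields on a 66×60 grid of
30 m pixels with a non-wheat background strip.  Irrigated sites follow a
dense supplemental schedule (roughly 8-day cadence through spring) that
keeps the growing-season stress factor ≥ 0.8; rain-fed sites receive none
and develop spring stress episodes.  Terrain is drawn per regime well clear
of the classification thresholds.

Scenes are rendered through the inverse of the retrieval chain plus
Gaussian sensor noise (reflectance SD 0.04, backscatter SD 1.9 dB), chosen
once so that scene-level retrieval errors land near 1 m² m⁻² (LAI) and
0.03 cm³ cm⁻³ (moisture) — the accuracy regime the method is designed for.
Because rendering inverts retrieval exactly at zero noise, the retrieval
stage is self-consistent by design and the twin experiments genuinely test
the assimilation and yield stages, not radiative transfer.  A
`render_bias` knob perturbs the rendering coefficients for model-mismatch
studies.

Per-site truth heterogeneity: a common *fertility* factor (CV 10%) scales
canopy potential and radiation-use efficiency together — vigorous fields
have both more leaf area and more yield — while water-supply factors vary
independently: field capacity (CV 9%), initial profile moisture drawn as a
common fraction U(0.75, 0.97) of each layer's field capacity (soils start
the season near a shared matric potential, so higher-capacity soils hold
proportionally more water), and slope-dependent rainfall runoff on
rain-fed fields.  Drawing initial moisture as a *fraction* of capacity
matters: an absolute draw independent of capacity makes field capacity
anti-correlated with yield (same water, larger stress denominator) while
still raising the topsoil reading, cancelling the moisture signal.  The
assimilating model always runs the *nominal* parameters, soil and initial
state: the classic imperfect-twin setup, since a perfect model would leave
assimilation nothing to correct.  Under this variance structure the LAI
composite carries the fertility signal in both regimes, while the moisture
composite carries substantial orthogonal yield information only where
water limits growth (truth-level partial R² ≈ 0.25 rain-fed vs ≈ 0.03
irrigated) — exactly the regime contrast the strategy comparison probes.

What passing twin experiments do **not** show: realism of radiative
transfer (no PROSAIL, no speckle, no topographic SAR effects), transfer of
the printed regression coefficients to other regions, or CERES-Wheat
equivalence.  They show that, given retrievals of the stated accuracy and
an imperfect crop model, the EnKF machinery reduces state errors and the
strategy ranking responds to water stress in the direction the method
predicts: LAI-only assimilation suffices where irrigation removes water
stress, and joint LAI + moisture assimilation is needed where it does not.

## Numerical choices and degenerate inputs

* Water-balance closure asserted at 1e-9 mm; WCM round trip at 1e-12;
  zero-noise scene round trips at 1e-6.
* Clamps: LAI ∈ [0, LAI_max]; θ ∈ [0, θ_sat] per layer; retrievals and
  yield predictions at ≥ 0; moisture retrieval ≤ 0.6.
* Degenerate inputs rejected with explicit errors: wilting point ≥ field
  capacity, non-increasing GDD thresholds, weather gaps (named date),
  observations outside the season, constant predictors, collinear joint
  predictors, fewer than 2 validation pairs, non-positive measured yields.
* All randomness flows from explicit seeds (scenario seed, assimilation
  seed); re-running a configuration is byte-identical.
* Problem sizes: the default twin replicate uses 45 sites, a 66×60 grid,
  100 ensemble members and a ~250-day season; unit tests use smaller grids
  (≈ 28×24, 11–13 sites, 30–60 members), which leave every code path
  identical while keeping the suite quick.
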