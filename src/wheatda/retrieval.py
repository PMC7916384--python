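"""Optical and SAR retrieval operators.

Vegetation indices (NDVI, NDWI), the semi-empirical water cloud model (WCM)
relating canopy backscatter to soil backscatter and plant water content, and
linear empirical retrievals mapping NDVI to LAI and soil backscatter (dB) to
volumetric soil moisture.

Unit conventions
----------------
The WCM operates in *linear power*; scene files carry backscatter in dB
(Sentinel-1 convention), so :func:`db_to_linear` / :func:`linear_to_db` are
explicit steps.  The soil-moisture regression is applied to soil backscatter
on the dB scale, where its coefficients produce physically plausible moisture
for typical (negative-dB) agricultural soils.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

EPS = 1e-12
#: two-way attenuation below which the canopy is treated as opaque and the
#: soil-backscatter inversion is masked rather than extrapolated
GAMMA2_MIN = 1e-3

#: winter-wheat canopy coefficients of the water cloud model
#: (Bindlish & Barros land-cover calibration)
WCM_WHEAT_A = 0.0018
WCM_WHEAT_B = 0.138

#: NDWI -> plant water content (kg m-2) quadratic (Jackson-type calibration)
MVEG_POLY = (1.44, 1.36, 0.34)  # a*NDWI^2 + b*NDWI + c

#: default clamp ranges applied after a linear retrieval
LAI_RANGE = (0.0, None)
SM_RANGE = (0.0, 0.6)


@dataclass
class OpticalScene:
    """Co-registered surface-reflectance rasters for one acquisition date."""

    date: dt.date
    red: "np.ndarray | object"
    nir: "np.ndarray | object"
    mir: "np.ndarray | object"


@dataclass
class SARScene:
    """Total canopy backscatter (dB) plus incidence angle for one date."""

    date: dt.date
    sigma_can_db: "np.ndarray | object"
    incidence_deg: float = 39.0


@dataclass(frozen=True)
class WCMParams:
    A: float = WCM_WHEAT_A  # vegetation scattering coefficient
    B: float = WCM_WHEAT_B  # attenuation coefficient per unit m_veg

    def __post_init__(self) -> None:
        if self.A < 0 or self.B <= 0:
            raise ValueError("require A >= 0 and B > 0")


@dataclass
class LinearRetrievalModel:
    """y = slope * x + intercept with fit provenance.

    target is "LAI" (m2 m-2, clamped at >= 0) or "SM" (cm3 cm-3, clamped to
    [0, 0.6]); the clamp is applied by :func:`apply_retrieval`.
    """

    slope: float
    intercept: float
    target: str  # "LAI" | "SM"
    r2: float = np.nan
    rmse: float = np.nan
    n: int = 0
    p_slope: float = np.nan
    fitted_on: dt.date | None = None

    def __post_init__(self) -> None:
        if self.target not in ("LAI", "SM"):
            raise ValueError("target must be 'LAI' or 'SM'")

    def to_dict(self) -> dict:
        return {
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "target": self.target,
            "r2": float(self.r2),
            "rmse": float(self.rmse),
            "n": int(self.n),
            "p_slope": float(self.p_slope),
            "fitted_on": None if self.fitted_on is None else self.fitted_on.isoformat(),
        }


def _masked_ratio(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    num = a - b
    den = a + b
    out = np.where(np.abs(den) > EPS, num / np.where(den == 0, 1.0, den), np.nan)
    if np.all(np.isnan(out)):
        raise ValueError("all pixels masked: empty result")
    return out


def ndvi(red, nir):
    """(NIR - RED)/(NIR + RED); NaN where the denominator vanishes or inputs are nodata."""
    return _masked_ratio(nir, red)


def ndwi(nir, mir):
    """(NIR - MIR)/(NIR + MIR), the shortwave water index."""
    return _masked_ratio(nir, mir)


def mveg_from_ndwi(ndwi_val):
    """Plant water content m_veg (kg m-2) from NDWI, clamped at >= 0."""
    x = np.asarray(ndwi_val, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((x < -1 - 1e-9) | (x > 1 + 1e-9)):
            raise ValueError("NDWI outside [-1, 1]")
    a, b, c = MVEG_POLY
    out = np.clip(a * x**2 + b * x + c, 0.0, None)
    return out if out.ndim else float(out)


def gamma2(m_veg, theta_inc_deg, params: WCMParams = WCMParams()):
    """Two-way canopy attenuation exp(-2 B m_veg sec(theta)), in (0, 1]."""
    theta = np.deg2rad(np.asarray(theta_inc_deg, dtype=float))
    if np.any(np.asarray(theta_inc_deg) >= 90) or np.any(np.asarray(theta_inc_deg) < 0):
        raise ValueError("incidence angle must be in [0, 90) degrees")
    return np.exp(-2.0 * params.B * np.asarray(m_veg, dtype=float) / np.cos(theta))


def wcm_forward(sigma_soil, m_veg, theta_inc_deg, params: WCMParams = WCMParams()):
    """Total canopy backscatter (linear power) from soil backscatter and m_veg."""
    m_veg = np.asarray(m_veg, dtype=float)
    if np.any(m_veg < 0):
        raise ValueError("m_veg must be non-negative")
    g2 = gamma2(m_veg, theta_inc_deg, params)
    theta = np.deg2rad(theta_inc_deg)
    sigma_veg = params.A * m_veg * np.cos(theta) * (1.0 - g2)
    out = sigma_veg + g2 * np.asarray(sigma_soil, dtype=float)
    return out if np.ndim(out) else float(out)


def wcm_invert(sigma_can, m_veg, theta_inc_deg, params: WCMParams = WCMParams()):
    """Soil backscatter (linear power): exact algebraic inverse of wcm_forward.

    Pixels whose two-way attenuation falls below GAMMA2_MIN (opaque canopy)
    are masked (NaN) rather than extrapolated.
    """
    m_veg = np.asarray(m_veg, dtype=float)
    g2 = gamma2(m_veg, theta_inc_deg, params)
    theta = np.deg2rad(theta_inc_deg)
    sigma_veg = params.A * m_veg * np.cos(theta) * (1.0 - g2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(g2 > GAMMA2_MIN, (np.asarray(sigma_can, dtype=float) - sigma_veg) / g2, np.nan)
    return out if np.ndim(out) else float(out)


def db_to_linear(x_db):
    out = 10.0 ** (np.asarray(x_db, dtype=float) / 10.0)
    return out if out.ndim else float(out)


def linear_to_db(x_lin):
    x = np.asarray(x_lin, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(x[np.isfinite(x)] <= 0):
            raise ValueError("linear power must be positive for dB conversion")
    return 10.0 * np.log10(x)


def fit_linear_retrieval(
    x, y, target: str, fitted_on: dt.date | None = None
) -> LinearRetrievalModel:
    """Ordinary least squares y ~ x for an empirical retrieval model.

    Reports slope, intercept, R^2, RMSE (root mean squared residual) and the
    slope's p-value.  Requires n >= 3 finite pairs and non-degenerate x.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 finite samples")
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid = y - res.fittedvalues
    return LinearRetrievalModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        target=target,
        r2=float(res.rsquared),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=len(x),
        p_slope=float(res.pvalues[1]),
        fitted_on=fitted_on,
    )


def apply_retrieval(model: LinearRetrievalModel, x):
    """slope*x + intercept with the target's physical clamp; NaN propagates."""
    x = np.asarray(x, dtype=float)
    raw = model.slope * x + model.intercept
    lo, hi = LAI_RANGE if model.target == "LAI" else SM_RANGE
    out = np.clip(raw, lo, hi)
    out = np.where(np.isnan(x), np.nan, out)
    return out if out.ndim else float(out)


def model_to_yaml(model: LinearRetrievalModel, path) -> None:
    """Serialise a fitted retrieval model with its provenance."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=True)


def model_from_yaml(path) -> LinearRetrievalModel:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fitted_on = raw.pop("fitted_on", None)
    if fitted_on:
        raw["fitted_on"] = dt.date.fromisoformat(fitted_on)
    return LinearRetrievalModel(**raw)


def lai_model_from_coefficients(
    slope: float = 8.8049, intercept: float = -0.9866
) -> LinearRetrievalModel:
    """NDVI -> LAI retrieval with externally calibrated coefficients."""
    return LinearRetrievalModel(slope=slope, intercept=intercept, target="LAI")


def sm_model_from_coefficients(
    slope: float = 0.0133, intercept: float = 0.3815
) -> LinearRetrievalModel:
    """Soil backscatter (dB) -> soil moisture retrieval with calibrated coefficients."""
    return LinearRetrievalModel(slope=slope, intercept=intercept, target="SM")
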