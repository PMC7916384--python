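"""Decision-tree winter-wheat mask and irrigated/rain-fed regime split.

Winter wheat is identified from three NDVI dates exploiting its phenology:
green canopy in mid-March and mid-April, harvested (bare) by June, with the
April NDVI exceeding the June one.  Wheat pixels at low elevation and gentle
slope are labelled irrigated; every other wheat pixel is rain-fed (the
complement rule, so the partition is exhaustive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import Raster

CLASS_CODES = {"non_wheat": 0, "irrigated": 1, "rain_fed": 2}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class TerrainGrid:
    elevation: Raster  # m
    slope: Raster  # degrees

    def __post_init__(self) -> None:
        self.elevation.require_aligned(self.slope, "elevation vs slope")
        s = self.slope.data
        if np.nanmin(s) < 0 or np.nanmax(s) > 90:
            raise ValueError("slope must be within [0, 90] degrees")


@dataclass
class RegimeMask:
    """Integer class raster (see CLASS_CODES) with known pixel area."""

    codes: Raster

    @property
    def pixel_area_ha(self) -> float:
        return self.codes.pixel_area_ha

    def count(self, label: str) -> int:
        return int(np.nansum(self.codes.data == CLASS_CODES[label]))


def slope_from_dem(dem: Raster) -> Raster:
    """Slope (degrees) from a DEM by central finite differences (Horn-style)."""
    z = dem.data
    dzdx = np.gradient(z, dem.pixel_size, axis=1)
    dzdy = np.gradient(z, dem.pixel_size, axis=0)
    return dem.like(np.degrees(np.arctan(np.hypot(dzdx, dzdy))))


def wheat_mask(
    ndvi_march: Raster,
    ndvi_april: Raster,
    ndvi_june: Raster,
    threshold: float = 0.25,
) -> Raster:
    """Boolean wheat raster from the three-date NDVI decision rule.

    wheat iff NDVI(Mar) > t AND NDVI(Apr) > t AND NDVI(Jun) < t AND
    NDVI(Apr) > NDVI(Jun).  Nodata in any date propagates.
    """
    ndvi_march.require_aligned(ndvi_april, "March vs April NDVI")
    ndvi_march.require_aligned(ndvi_june, "March vs June NDVI")
    a, b, c = ndvi_march.data, ndvi_april.data, ndvi_june.data
    wheat = (a > threshold) & (b > threshold) & (c < threshold) & (b > c)
    out = wheat.astype(float)
    out[np.isnan(a) | np.isnan(b) | np.isnan(c)] = np.nan
    return ndvi_march.like(out)


def regime_split(
    wheat: Raster,
    terrain: TerrainGrid,
    elev_thresh: float = 600.0,
    slope_thresh: float = 15.0,
) -> RegimeMask:
    """Split wheat pixels into irrigated (<elev_thresh m and <slope_thresh deg)
    and rain-fed (all remaining wheat pixels)."""
    wheat.require_aligned(terrain.elevation, "wheat vs terrain")
    is_wheat = wheat.data == 1
    irr = is_wheat & (terrain.elevation.data < elev_thresh) & (
        terrain.slope.data < slope_thresh
    )
    codes = np.where(irr, CLASS_CODES["irrigated"], CLASS_CODES["non_wheat"]).astype(float)
    codes[is_wheat & ~irr] = CLASS_CODES["rain_fed"]
    codes[np.isnan(wheat.data)] = np.nan
    return RegimeMask(wheat.like(codes))


def class_areas(mask: RegimeMask) -> pd.DataFrame:
    """Area (ha) per class and share (%) of the wheat total, one decimal.

    With an empty wheat mask the shares are NaN and a warning is issued.
    """
    rows = []
    for label in ("irrigated", "rain_fed"):
        n = mask.count(label)
        rows.append({"class": label, "pixels": n, "area_ha": n * mask.pixel_area_ha})
    df = pd.DataFrame(rows)
    total = df["area_ha"].sum()
    if total == 0:
        warnings.warn("empty wheat mask: regime shares undefined")
        df["share_pct"] = np.nan
    else:
        df["share_pct"] = (100.0 * df["area_ha"] / total).round(1)
    return df


def shares_from_areas(irrigated_ha: float, rain_fed_ha: float) -> tuple[float, float]:
    """Regime shares (%) of the wheat total from printed areas, one decimal."""
    total = irrigated_ha + rain_fed_ha
    if total <= 0:
        raise ValueError("total wheat area must be positive")
    return (
        round(100.0 * irrigated_ha / total, 1),
        round(100.0 * rain_fed_ha / total, 1),
    )
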