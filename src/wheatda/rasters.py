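"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Scenes and masks are small desk-scale grids; NaN marks nodata throughout the
package and every raster operation propagates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster on a regular grid.

    Parameters
    ----------
    data : 2-D float array; NaN encodes nodata.
    pixel_size : cell edge length in metres (square cells).
    origin : (x, y) of the lower-left corner in an arbitrary planar CRS.
    """

    data: np.ndarray
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the pixel is nodata."""
        return np.isnan(self.data)

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 10_000.0

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_aligned(self, other: "Raster", what: str = "raster") -> None:
        if not self.aligned_with(other):
            raise ValueError(f"misaligned grids: {what}")

    def like(self, data: np.ndarray) -> "Raster":
        """New raster on this grid carrying `data`."""
        if np.shape(data) != self.shape:
            raise ValueError("data shape does not match grid")
        return Raster(np.asarray(data, dtype=float), self.pixel_size, self.origin)

    # ---- text I/O (ESRI ASCII grid) -------------------------------------

    def write_ascii(self, path) -> None:
        nrows, ncols = self.shape
        out = np.where(np.isnan(self.data), NODATA, self.data)
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.origin[0]}\n"
            f"yllcorner {self.origin[1]}\n"
            f"cellsize {self.pixel_size}\n"
            f"NODATA_value {NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = meta.get("nodata_value", NODATA)
        data[data == nodata] = np.nan
        return cls(
            data,
            pixel_size=meta["cellsize"],
            origin=(meta["xllcorner"], meta["yllcorner"]),
        )
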