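"""Single-band rasters, NDVI computation and the NDVI-to-LAI inversion.

Rasters are plain 2-D float grids with a north-up geotransform (origin at
the top-left pixel corner, square pixels) and NaN as the internal nodata
marker.  They are stored as single-band TIFFs with the georeferencing and
acquisition date serialized as JSON in the image description tag.

The NDVI-to-LAI step uses a semi-empirical site relationship established
for cereal crops.  Its coefficients are site-specific and must be supplied
by the user; the module ships a clearly flagged placeholder default
(linear, lai = 4.0*ndvi - 0.8, valid for NDVI in [0.2, 0.95]) that anchors
LAI 0 at the lower validity bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import tifffile

__all__ = [
    "BandRaster",
    "NdviLaiRelation",
    "PLACEHOLDER_NDVI_LAI",
    "compute_ndvi",
    "ndvi_to_lai",
    "read_raster",
    "write_raster",
]


@dataclass(frozen=True)
class BandRaster:
    """One band on a regular north-up grid; NaN marks nodata."""

    data: np.ndarray
    pixel_size: float = 10.0  # m
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the top-left corner
    date: str | None = None  # ISO acquisition date

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "BandRaster") -> bool:
        return (
            self.shape == other.shape
            and self.pixel_size == other.pixel_size
            and self.origin == other.origin
        )


@dataclass(frozen=True)
class NdviLaiRelation:
    """Monotone NDVI -> LAI mapping with a validity range.

    ``form`` is "linear" (lai = a*ndvi + b) or "exponential"
    (lai = a*(exp(b*ndvi) - 1)).  NDVI below the validity range maps to
    LAI 0; above it the mapping saturates at the upper bound's value.
    """

    form: str
    a: float
    b: float
    ndvi_range: tuple[float, float] = (0.2, 0.95)
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("linear", "exponential"):
            raise ValueError(f"unknown relation form {self.form!r}")
        lo, hi = self.ndvi_range
        if not -1.0 <= lo < hi <= 1.0:
            raise ValueError("ndvi validity range must satisfy -1 <= lo < hi <= 1")
        grid = np.linspace(lo, hi, 64)
        vals = self._raw(grid)
        if (np.diff(vals) < 0).any() or (vals < 0).any():
            raise ValueError("relation must be non-decreasing and non-negative on its validity range")

    def _raw(self, ndvi):
        if self.form == "linear":
            return self.a * ndvi + self.b
        return self.a * np.expm1(self.b * ndvi)

    def __call__(self, ndvi):
        ndvi = np.asarray(ndvi, dtype=float)
        clipped = np.clip(ndvi, *self.ndvi_range)
        lai = np.maximum(self._raw(clipped), 0.0)
        lai = np.where(ndvi < self.ndvi_range[0], 0.0, lai)
        return np.where(np.isnan(ndvi), np.nan, lai)

    @classmethod
    def from_dict(cls, d: dict) -> "NdviLaiRelation":
        return cls(
            form=d["form"], a=float(d["a"]), b=float(d["b"]),
            ndvi_range=tuple(d.get("ndvi_range", (0.2, 0.95))),
            placeholder=bool(d.get("placeholder", False)),
        )


#: Stand-in coefficients for sites without an established relationship;
#: not derived from any field campaign — replace with locally fitted values.
PLACEHOLDER_NDVI_LAI = NdviLaiRelation(
    form="linear", a=4.0, b=-0.8, ndvi_range=(0.2, 0.95), placeholder=True
)


def compute_ndvi(red: BandRaster, nir: BandRaster) -> BandRaster:
    """(NIR - Red) / (NIR + Red); zero-denominator pixels become nodata."""
    if not red.same_grid(nir):
        raise ValueError("red and nir rasters are not on the same grid")
    r, n = red.data, nir.data
    for name, band in (("red", r), ("nir", n)):
        valid = band[~np.isnan(band)]
        if ((valid < 0) | (valid > 1)).any():
            raise ValueError(f"{name} reflectance outside [0, 1]")
    denom = n + r
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom == 0, np.nan, (n - r) / denom)
    return replace(red, data=ndvi, date=red.date or nir.date)


def ndvi_to_lai(ndvi: BandRaster, rel: NdviLaiRelation | None) -> BandRaster:
    """Apply the NDVI-to-LAI relation per pixel, propagating nodata."""
    if rel is None:
        raise ValueError(
            "no NDVI-to-LAI relation configured: supply site coefficients "
            "(form, a, b, ndvi_range) fitted for your cereal crops"
        )
    return replace(ndvi, data=rel(ndvi.data))


def write_raster(raster: BandRaster, path) -> None:
    meta = {
        "pixel_size": raster.pixel_size,
        "origin": list(raster.origin),
        "date": raster.date,
        "nodata": "nan",
    }
    tifffile.imwrite(path, raster.data.astype("float32"), description=json.dumps(meta))


def read_raster(path) -> BandRaster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    return BandRaster(
        data=data,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        date=meta.get("date"),
    )
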