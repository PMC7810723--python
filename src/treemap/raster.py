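"""Minimal georeferenced raster container and text-grid I/O.

Rasters are square-pixel, north-up grids stored on disk as ESRI ASCII
grids (``.asc``) with a one-line CRS sidecar (``.crs``).  Two coordinate
reference systems are supported:

* ``EPSG:4326`` — projected coordinates *are* geographic degrees
  (x = longitude, y = latitude).
* ``AEQD:<lat0>:<lon0>`` — a local azimuthal-equidistant projection on
  the authalic sphere, in metres, centred on (lat0, lon0).  This is the
  natural frame for a desk-scale landscape: Euclidean distances near the
  origin are true ground distances.

Pixel convention: row 0 is the northern edge, column 0 the western edge;
a pixel covers the half-open square [origin, origin + size) and its
centroid sits at origin + (index + 0.5) * size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: mean radius of the sphere used by the local AEQD projection (metres)
EARTH_RADIUS_M = 6_371_008.8


class RasterAlignmentError(ValueError):
    """Two bands that must be co-registered are not (exact-equality check)."""


class CRSError(ValueError):
    """Missing or unparseable coordinate reference system."""


@dataclass(frozen=True)
class GridGeometry:
    """Affine placement of a north-up, square-pixel grid.

    ``x_origin``/``y_origin`` locate the *outer corner* of pixel (0, 0),
    i.e. the north-west corner of the grid, in projected units.
    """

    x_origin: float
    y_origin: float
    pixel_size: float
    nrows: int
    ncols: int

    def pixel_center(self, row, col):
        """Projected coordinates of pixel centroids (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_origin + (col + 0.5) * self.pixel_size
        y = self.y_origin - (row + 0.5) * self.pixel_size
        return x, y

    def index_of(self, x, y):
        """Row/col of the pixel containing projected point(s) (half-open)."""
        x = np.asarray(x)
        y = np.asarray(y)
        col = np.floor((x - self.x_origin) / self.pixel_size).astype(int)
        row = np.floor((self.y_origin - y) / self.pixel_size).astype(int)
        return row, col

    def contains(self, x, y):
        row, col = self.index_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)


@dataclass
class RasterBand:
    """One single-band raster: values + nodata sentinel + georeference."""

    values: np.ndarray
    nodata: float
    geometry: GridGeometry
    crs: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.values.shape != (self.geometry.nrows, self.geometry.ncols):
            raise RasterAlignmentError(
                f"value shape {self.values.shape} does not match geometry "
                f"({self.geometry.nrows}, {self.geometry.ncols})"
            )

    @property
    def shape(self):
        return self.values.shape

    def mask_valid(self):
        return self.values != self.nodata

    def like(self, values, nodata=None):
        """A new band sharing this band's georeference."""
        return RasterBand(values, self.nodata if nodata is None else nodata,
                          self.geometry, self.crs)


def check_aligned(*bands: RasterBand) -> None:
    """Raise unless all bands share geometry and CRS exactly.

    Alignment is exact equality, never tolerance matching: a misaligned
    stack is an input error, not something to resample silently.
    """
    first = bands[0]
    for b in bands[1:]:
        if b.geometry != first.geometry or b.crs != first.crs:
            raise RasterAlignmentError(
                f"band geometry/CRS mismatch: {b.geometry}/{b.crs} vs "
                f"{first.geometry}/{first.crs}"
            )


# ---------------------------------------------------------------------------
# projections

def _parse_aeqd(crs: str):
    parts = crs.split(":")
    if len(parts) != 3:
        raise CRSError(f"cannot parse AEQD CRS {crs!r}; expected AEQD:lat0:lon0")
    return float(parts[1]), float(parts[2])


def to_geographic(crs: str, x, y):
    """Inverse-project planar coordinates to (latitude, longitude) degrees."""
    if not crs:
        raise CRSError("raster has no CRS; geographic coordinates undefined")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if crs.upper() == "EPSG:4326":
        return y, x
    if crs.upper().startswith("AEQD:"):
        lat0, lon0 = _parse_aeqd(crs)
        phi0 = np.radians(lat0)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_M
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.arcsin(
                np.cos(c) * np.sin(phi0)
                + np.where(rho > 0, y * np.sin(c) * np.cos(phi0) / rho, 0.0)
            )
            lam = np.radians(lon0) + np.arctan2(
                x * np.sin(c),
                rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
            )
        lat = np.where(rho > 0, np.degrees(phi), lat0)
        lon = np.where(rho > 0, np.degrees(lam), lon0)
        if lat.ndim == 0:
            return float(lat), float(lon)
        return lat, lon
    raise CRSError(f"unsupported CRS {crs!r}")


def from_geographic(crs: str, lat, lon):
    """Forward-project (latitude, longitude) degrees to planar coordinates."""
    if not crs:
        raise CRSError("raster has no CRS; cannot project")
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if crs.upper() == "EPSG:4326":
        return np.asarray(lon, dtype=float), np.asarray(lat, dtype=float)
    if crs.upper().startswith("AEQD:"):
        lat0, lon0 = _parse_aeqd(crs)
        phi0, phi = np.radians(lat0), np.radians(lat)
        dlam = np.radians(lon - lon0)
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 0, c / np.sin(c), 1.0)
        x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_M * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
        )
        if x.ndim == 0:
            return float(x), float(y)
        return x, y
    raise CRSError(f"unsupported CRS {crs!r}")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(band: RasterBand, path) -> None:
    """Write a band as an ESRI ASCII grid plus a ``.crs`` sidecar."""
    path = Path(path)
    geo = band.geometry
    yll = geo.y_origin - geo.nrows * geo.pixel_size
    vals = band.values
    integral = np.issubdtype(vals.dtype, np.integer)
    fmt = "%d" if integral else "%.10g"
    nodata = int(band.nodata) if integral else band.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {geo.ncols}\n")
        fh.write(f"nrows {geo.nrows}\n")
        fh.write(f"xllcorner {geo.x_origin:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {geo.pixel_size:.10g}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, vals, fmt=fmt)
    if band.crs:
        path.with_suffix(".crs").write_text(band.crs + "\n")


def read_ascii_grid(path, dtype=None) -> RasterBand:
    """Read an ESRI ASCII grid; the CRS comes from the ``.crs`` sidecar."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = val
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    size = float(header["cellsize"])
    geo = GridGeometry(
        x_origin=float(header["xllcorner"]),
        y_origin=float(header["yllcorner"]) + nrows * size,
        pixel_size=size,
        nrows=nrows,
        ncols=ncols,
    )
    nodata = float(header.get("nodata_value", -9999))
    if dtype is not None:
        values = values.astype(dtype)
        nodata = np.array(nodata).astype(dtype).item()
    crs_path = path.with_suffix(".crs")
    crs = crs_path.read_text().strip() if crs_path.exists() else ""
    return RasterBand(values, nodata, geo, crs)
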