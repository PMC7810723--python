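"""Preprocessing of raw landscape rasters into an analysis-ready stack.

The imputation engine consumes a :class:`TargetStack`: a set of
co-registered bands holding the response surfaces (canopy-cover bin,
canopy-height bin, vegetation group), the predictor surfaces
(topography, six biophysical gradients, disturbance code/year, pixel
latitude/longitude) and a boolean forest mask.  This module owns the
recoding rules that turn raw surfaces into those bands:

* percent canopy cover -> midpoint of its 10-point bin (15 ... 95);
  pixels under 10 % cover are non-forest and fall out of the mask;
* dominant-vegetation height -> one of five bin values (3, 8, 18, 38,
  70 m);
* a sequence of annual disturbance layers -> a single most-recent
  disturbance code/year pair, with fire taking precedence over
  insect/disease regardless of recency;
* vegetation-group substitutions from a config-driven recode table
  (classes without any reference plot must be recoded to a similar
  class or dropped, since a categorical class unseen in the reference
  set can never be imputed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .raster import GridGeometry, RasterBand, check_aligned, read_ascii_grid, to_geographic, write_ascii_grid

COVER_BIN_MIDPOINTS = (15, 25, 35, 45, 55, 65, 75, 85, 95)
HEIGHT_BIN_VALUES = (3, 8, 18, 38, 70)
#: lower edges of the height bins, half-open [lo, hi), top bin unbounded
HEIGHT_BIN_EDGES = (0.0, 5.0, 10.0, 25.0, 50.0)

DIST_NONE = 0
DIST_FIRE = 1
DIST_INSECT = 2
#: dist_year value on undisturbed pixels/plots; 0 is distinct from all
#: valid calendar years and keeps the band numeric for tree splits
DIST_YEAR_SENTINEL = 0

MIN_FOREST_COVER_PCT = 10.0

RESPONSE_BANDS = ("cover_bin", "height_bin", "evg")
BIOPHYSICAL_BANDS = ("par", "precip", "rh", "tmax", "tmin", "vpd")
PREDICTOR_BANDS = ("lat", "lon", "slope", "aspect", "elevation") + BIOPHYSICAL_BANDS + ("dist_code", "dist_year")
ALL_BANDS = RESPONSE_BANDS + PREDICTOR_BANDS
CATEGORICAL_VARS = frozenset({"evg", "dist_code"})


class NonForestError(ValueError):
    """Cover below the 10 % forest threshold; the pixel/plot is excluded."""


class InvalidRecordError(ValueError):
    pass


class UnresolvedClassError(ValueError):
    """A masked pixel carries a vegetation-group code with no reference plot."""


def bin_cover(cover_percent):
    """Midpoint of the 10-point cover bin containing ``cover_percent``.

    Bins are half-open [lo, hi) with the bottom edge of the lowest
    forest bin (10 %) inclusive and the top bin closed at 100 %.
    Values below 10 % signal non-forest and raise.
    """
    x = np.asarray(cover_percent, dtype=float)
    if np.any(x < MIN_FOREST_COVER_PCT):
        raise NonForestError("cover below 10% is non-forest; exclude the pixel")
    if np.any(x > 100.0):
        raise ValueError("cover percent above 100")
    mid = (np.floor(x / 10.0) * 10 + 5).astype(int)
    mid = np.minimum(mid, 95)  # 100% belongs to the closed top bin
    return mid if mid.ndim else int(mid)


def bin_height(height_m):
    """Representative value of the height bin containing ``height_m``.

    Five bins, half-open [lo, hi), the top bin unbounded above: 0-5 m
    -> 3, 5-10 -> 8, 10-25 -> 18, 25-50 -> 38, >=50 -> 70.
    """
    x = np.asarray(height_m, dtype=float)
    if np.any(x < 0):
        raise InvalidRecordError("negative height")
    idx = np.searchsorted(HEIGHT_BIN_EDGES, x, side="right") - 1
    out = np.asarray(HEIGHT_BIN_VALUES)[idx]
    return out if out.ndim else int(out)


def collapse_disturbance(annual_layers):
    """Collapse per-year disturbance-type layers into (code, year) bands.

    ``annual_layers`` is a sequence of ``(year, type_array)`` pairs where
    the type array codes 0 = none, 1 = fire, 2 = insect/disease for that
    year.  Per pixel: any fire wins with its most recent fire year;
    otherwise the most recent insect/disease year; otherwise code 0 and
    the sentinel year.  The result is invariant to layer order.
    """
    pairs = list(annual_layers)
    if not pairs:
        raise ValueError("no disturbance layers given")
    if isinstance(pairs[0][1], RasterBand):
        check_aligned(*[t for _, t in pairs])
    layers = [(int(y), np.asarray(t.values if isinstance(t, RasterBand) else t)) for y, t in pairs]
    years = [y for y, _ in layers]
    if len(set(years)) != len(years):
        raise ValueError("duplicate disturbance years")
    shape = layers[0][1].shape
    for _, arr in layers:
        if arr.shape != shape:
            from .raster import RasterAlignmentError
            raise RasterAlignmentError("disturbance layers have inconsistent shapes")
    fire_year = np.zeros(shape, dtype=int)
    insect_year = np.zeros(shape, dtype=int)
    for year, arr in sorted(layers):
        fire_year = np.where(arr == DIST_FIRE, year, fire_year)
        insect_year = np.where(arr == DIST_INSECT, year, insect_year)
    code = np.where(fire_year > 0, DIST_FIRE, np.where(insect_year > 0, DIST_INSECT, DIST_NONE))
    year = np.where(fire_year > 0, fire_year, np.where(insect_year > 0, insect_year, DIST_YEAR_SENTINEL))
    return code, year


DROP = "DROP"


@dataclass
class EvgRecodeTable:
    """Vegetation-group substitutions: source code -> target code or DROP."""

    mapping: dict[int, object] = field(default_factory=dict)

    def __post_init__(self):
        # reject cycles up front so resolve() always terminates
        for code in self.mapping:
            self.resolve(code)

    def resolve(self, code: int):
        """Follow the recode chain; returns the final code or ``DROP``."""
        seen = set()
        while code in self.mapping:
            if code in seen:
                raise ValueError(f"recode cycle involving EVG {code}")
            seen.add(code)
            target = self.mapping[code]
            if target == DROP:
                return DROP
            code = int(target)
        return code

    @classmethod
    def from_csv(cls, path) -> "EvgRecodeTable":
        mapping = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                src = int(row["source_evg"])
                tgt = row["target_evg_or_DROP"].strip()
                mapping[src] = DROP if tgt.upper() == DROP else int(tgt)
        return cls(mapping)

    @classmethod
    def default(cls) -> "EvgRecodeTable":
        """The stock substitutions for the 2014 CONUS landscape."""
        return cls.from_csv(Path(__file__).parent / "data" / "evg_recode_default.csv")


def build_forest_mask(cover_band: RasterBand, evg_band: RasterBand,
                      recode_table: EvgRecodeTable | None = None,
                      excluded_evgs=(), reference_evgs=None):
    """Forest mask + recoded vegetation-group raster.

    A pixel is forest when its cover is at least 10 %, its vegetation
    group is not developed/agricultural (``excluded_evgs``) and the
    recode table does not drop it.  When ``reference_evgs`` (the set of
    vegetation groups with at least one reference plot) is supplied,
    any masked pixel whose recoded group lies outside it raises
    :class:`UnresolvedClassError` — the hard constraint of categorical
    imputation.
    """
    check_aligned(cover_band, evg_band)
    recode_table = recode_table or EvgRecodeTable()
    cover = np.asarray(cover_band.values, dtype=float)
    evg = np.asarray(evg_band.values).astype(int)

    recoded = evg.copy()
    dropped = np.zeros(evg.shape, dtype=bool)
    for code in np.unique(evg):
        target = recode_table.resolve(int(code))
        sel = evg == code
        if target == DROP:
            dropped |= sel
        else:
            recoded[sel] = target

    mask = (cover >= MIN_FOREST_COVER_PCT) & ~dropped
    mask &= cover != cover_band.nodata
    mask &= evg != int(evg_band.nodata)
    if excluded_evgs:
        mask &= ~np.isin(recoded, list(excluded_evgs))

    if reference_evgs is not None:
        present = np.unique(recoded[mask])
        missing = sorted(set(int(c) for c in present) - set(int(c) for c in reference_evgs))
        if missing:
            raise UnresolvedClassError(
                f"masked pixels carry EVG codes with no reference plot: {missing}; "
                "recode or drop them before imputation"
            )
    mask_band = cover_band.like(mask.astype(np.uint8), nodata=255)
    evg_out = evg_band.like(recoded)
    return mask_band, evg_out


def pixel_centroids(geometry: GridGeometry, crs: str):
    """Latitude/longitude rasters of every pixel's centroid."""
    rows, cols = np.meshgrid(np.arange(geometry.nrows), np.arange(geometry.ncols), indexing="ij")
    x, y = geometry.pixel_center(rows, cols)
    lat, lon = to_geographic(crs, x, y)
    return np.asarray(lat), np.asarray(lon)


# ---------------------------------------------------------------------------
# the analysis-ready stack

@dataclass
class TargetStack:
    """Co-registered analysis-ready bands plus the forest mask.

    ``bands`` maps role names (see :data:`ALL_BANDS`) to 2-D arrays;
    ``mask`` is boolean.  All arrays share ``geometry``/``crs``.
    """

    bands: dict[str, np.ndarray]
    mask: np.ndarray
    geometry: GridGeometry
    crs: str
    nodata: float = -9999.0

    def __post_init__(self):
        shape = (self.geometry.nrows, self.geometry.ncols)
        for name, arr in self.bands.items():
            if np.asarray(arr).shape != shape:
                from .raster import RasterAlignmentError
                raise RasterAlignmentError(f"band {name!r} shape {arr.shape} != {shape}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self):
        return self.mask.shape

    def masked_indices(self):
        """(row, col) arrays of forested pixels in row-major order."""
        return np.nonzero(self.mask)

    def pixel_matrix(self, var_names):
        """(n_masked, k) matrix of band values at forested pixels, row-major."""
        rows, cols = self.masked_indices()
        return np.column_stack([np.asarray(self.bands[v], dtype=float)[rows, cols] for v in var_names])

    def band(self, name):
        return np.asarray(self.bands[name])

    def validate(self):
        """Check the stack's internal consistency; raises on violation."""
        cover = self.band("cover_bin")[self.mask]
        if not np.isin(cover, COVER_BIN_MIDPOINTS).all():
            raise ValueError("masked cover_bin outside the nine forest bins")
        height = self.band("height_bin")[self.mask]
        if not np.isin(height, HEIGHT_BIN_VALUES).all():
            raise ValueError("masked height_bin outside the five bins")
        code = self.band("dist_code")
        year = self.band("dist_year")
        if not ((code == DIST_NONE) == (year == DIST_YEAR_SENTINEL)).all():
            raise ValueError("dist_code=0 must pair with the sentinel year")

    # -- persistence -------------------------------------------------------

    def to_dir(self, out_dir):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"crs": self.crs, "nodata": self.nodata, "bands": {}}
        for name in (*self.bands.keys(), "forest_mask"):
            arr = self.mask.astype(np.uint8) if name == "forest_mask" else np.asarray(self.bands[name])
            if arr.dtype == bool:
                arr = arr.astype(np.uint8)
            band = RasterBand(arr, 255 if name == "forest_mask" else self.nodata, self.geometry, self.crs)
            fname = f"{name}.asc"
            write_ascii_grid(band, out_dir / fname)
            manifest["bands"][name] = fname
        with open(out_dir / "stack.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)

    @classmethod
    def from_dir(cls, in_dir) -> "TargetStack":
        in_dir = Path(in_dir)
        with open(in_dir / "stack.yaml") as fh:
            manifest = yaml.safe_load(fh)
        bands = {}
        mask = None
        geometry = crs = None
        int_bands = set(RESPONSE_BANDS) | {"dist_code", "dist_year"}
        for name, fname in manifest["bands"].items():
            dtype = int if name in int_bands or name == "forest_mask" else float
            band = read_ascii_grid(in_dir / fname, dtype=dtype)
            if geometry is None:
                geometry, crs = band.geometry, band.crs or manifest.get("crs", "")
            if name == "forest_mask":
                mask = band.values.astype(bool)
            else:
                bands[name] = band.values
        stack = cls(bands, mask, geometry, crs, nodata=manifest.get("nodata", -9999.0))
        check_aligned(*[RasterBand(np.zeros(stack.shape), 0, geometry, crs)])
        return stack


def prepare_target_stack(cover_percent: RasterBand, height_m: RasterBand,
                         evg: RasterBand, slope: RasterBand, aspect: RasterBand,
                         elevation: RasterBand, biophysical: dict[str, RasterBand],
                         annual_disturbance, recode_table: EvgRecodeTable | None = None,
                         excluded_evgs=(), reference_evgs=None) -> TargetStack:
    """Full preprocessing chain: mask, recode, bin, collapse, locate.

    ``annual_disturbance`` is a sequence of ``(year, RasterBand)`` pairs
    (may be empty).  Returns a validated :class:`TargetStack`.
    """
    bio_bands = [biophysical[k] for k in BIOPHYSICAL_BANDS]
    check_aligned(cover_percent, height_m, evg, slope, aspect, elevation, *bio_bands)
    mask_band, evg_recoded = build_forest_mask(
        cover_percent, evg, recode_table, excluded_evgs, reference_evgs)
    mask = mask_band.values.astype(bool)

    cover_vals = np.asarray(cover_percent.values, dtype=float)
    cover_bin = np.full(cover_vals.shape, 0, dtype=int)
    cover_bin[mask] = bin_cover(cover_vals[mask])
    height_bin = np.full(cover_vals.shape, 0, dtype=int)
    height_bin[mask] = bin_height(np.asarray(height_m.values, dtype=float)[mask])

    annual_disturbance = list(annual_disturbance)
    if annual_disturbance:
        check_aligned(cover_percent, *[b for _, b in annual_disturbance])
        dist_code, dist_year = collapse_disturbance(annual_disturbance)
    else:
        dist_code = np.zeros(cover_vals.shape, dtype=int)
        dist_year = np.full(cover_vals.shape, DIST_YEAR_SENTINEL, dtype=int)

    lat, lon = pixel_centroids(cover_percent.geometry, cover_percent.crs)
    bands = {
        "cover_bin": cover_bin,
        "height_bin": height_bin,
        "evg": evg_recoded.values,
        "slope": np.asarray(slope.values, dtype=float),
        "aspect": np.asarray(aspect.values, dtype=float),
        "elevation": np.asarray(elevation.values, dtype=float),
        **{k: np.asarray(biophysical[k].values, dtype=float) for k in BIOPHYSICAL_BANDS},
        "dist_code": dist_code,
        "dist_year": dist_year,
        "lat": lat,
        "lon": lon,
    }
    stack = TargetStack(bands, mask, cover_percent.geometry, cover_percent.crs)
    stack.validate()
    return stack
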