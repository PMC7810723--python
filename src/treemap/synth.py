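"""Seeded synthetic landscapes and plot networks with known ground truth.

The generator emulates the structure of the real inputs end to end: a
stack of co-registered 30 m rasters (smooth elevation/biophysical
gradients, blocky vegetation-group regions, disc-shaped disturbance
patches with calendar years) and a plot network whose tree lists are
*constructed* so that the derived plot attributes (overlap-corrected
canopy cover, nine-tree top-stratum height, top-two species by basal
area) land in each plot's assigned bins.  Every pixel carries a known
generating plot, so recovery of plot identity and attributes by the
imputation engine can be asserted against truth.

What it deliberately does not mimic: real geography, the spatial
autocovariance of real vegetation mosaics, inventory sampling design,
measurement error structure, or multi-stratum canopies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .plots import SQ_M_PER_ACRE, SQ_M_PER_HECTARE
from .raster import GridGeometry, RasterBand
from .target_prep import (
    DIST_FIRE,
    DIST_INSECT,
    HEIGHT_BIN_VALUES,
    TargetStack,
    bin_cover,
    bin_height,
    collapse_disturbance,
    prepare_target_stack,
)

_POOLS_CSV = Path(__file__).parent / "data" / "species_pools.csv"


def species_pools() -> dict[int, list[int]]:
    """The packaged vegetation-group -> species-code pools."""
    frame = pd.read_csv(_POOLS_CSV)
    return {int(evg): grp["spcd"].astype(int).tolist() for evg, grp in frame.groupby("evg")}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic landscape.

    Defaults are the desk-scale fixture: a 200x200 grid of 30 m pixels
    (6 x 6 km), 500 reference plots over 12 vegetation groups, smooth
    biophysical fields with a 10-pixel correlation length, and small
    attribute noise (0.5 cover points, 0.3 m height) between a pixel
    and its generating plot — emulating a classified, spatially
    coherent target product whose classes are largely determined by the
    mapped gradients.
    """

    shape: tuple = (200, 200)
    pixel_size_m: float = 30.0
    n_plots: int = 500
    n_evg: int = 12
    correlation_length_px: float = 10.0
    cover_noise_sd: float = 0.5
    height_noise_sd: float = 0.3
    n_disturbance_patches: int = 6
    patch_radius_px: float = 12.0
    disturbance_years: tuple = (1999, 2014)
    mean_live_trees: float = 12.0
    dead_base_mean: float = 1.0
    fire_dead_extra: float = 5.0
    insect_dead_extra: float = 3.0
    n_validation_plots: int = 100
    validation_noise_sd: float = 6.0
    tpa_unit: str = "per_acre"
    origin_lat: float = 45.0
    origin_lon: float = -114.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_evg > 32:
            raise ValueError("at most 32 vegetation-group classes")
        if self.n_plots < self.n_evg:
            raise ValueError("need at least one plot per vegetation group")
        for sd in (self.cover_noise_sd, self.height_noise_sd, self.validation_noise_sd):
            if sd < 0:
                raise ValueError("noise sd must be >= 0")

    @property
    def crs(self) -> str:
        return f"AEQD:{self.origin_lat:g}:{self.origin_lon:g}"

    def geometry(self) -> GridGeometry:
        nrows, ncols = self.shape
        return GridGeometry(
            x_origin=-0.5 * ncols * self.pixel_size_m,
            y_origin=0.5 * nrows * self.pixel_size_m,
            pixel_size=self.pixel_size_m, nrows=nrows, ncols=ncols)


@dataclass
class TruthMap:
    """Per-pixel generating plot and per-plot true attributes."""

    gen_plot_id: np.ndarray
    plot_truth: pd.DataFrame


@dataclass
class SynthResult:
    stack: TargetStack
    truth: TruthMap
    plot_table: pd.DataFrame
    tree_table: pd.DataFrame
    config: SynthConfig = field(repr=False, default=None)


def _smooth_field(rng, shape, corr_len, mean, amplitude):
    f = gaussian_filter(rng.normal(size=shape), sigma=corr_len, mode="reflect")
    sd = f.std()
    if sd > 0:
        f = f / sd
    return mean + amplitude * f


def generate_landscape(config: SynthConfig | None = None):
    """Build the raster stack and the pixel -> generating-plot truth.

    Returns ``(TargetStack, TruthMap)``.  The stack is produced by the
    real preprocessing chain (binning, disturbance collapse, masking,
    centroid computation), not assembled by hand.
    """
    config = config or SynthConfig()
    ss = np.random.SeedSequence([int(config.rng_seed), 11])
    r_field, r_evg, r_plot, r_noise, r_dist = [np.random.default_rng(s) for s in ss.spawn(5)]
    nrows, ncols = config.shape
    geo = config.geometry()
    crs = config.crs
    px = config.pixel_size_m
    cl = config.correlation_length_px

    # independent smooth surfaces: each biophysical band carries its own
    # information, so together they resolve fine environmental detail
    elevation = _smooth_field(r_field, config.shape, cl, 1500.0, 400.0)
    gy, gx = np.gradient(elevation, px)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect = np.degrees(np.arctan2(-gx, gy)) % 360.0
    biophys = {
        "par": _smooth_field(r_field, config.shape, cl, 450.0, 80.0),
        "precip": _smooth_field(r_field, config.shape, cl, 800.0, 300.0),
        "rh": _smooth_field(r_field, config.shape, cl, 50.0, 15.0),
        "tmax": _smooth_field(r_field, config.shape, cl, 18.0, 5.0),
        "tmin": _smooth_field(r_field, config.shape, cl, 2.0, 4.0),
        "vpd": _smooth_field(r_field, config.shape, cl, 12.0, 4.0),
    }

    pools = species_pools()
    evg_codes = sorted(pools)[: config.n_evg]
    if len(evg_codes) < config.n_evg:
        raise ValueError("not enough vegetation groups in the species pools")
    seeds = np.column_stack([r_evg.uniform(0, nrows, config.n_evg),
                             r_evg.uniform(0, ncols, config.n_evg)])
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()])
    region = cKDTree(seeds).query(pix)[1].reshape(config.shape)
    evg = np.asarray(evg_codes)[region]

    # plot network: one plot per vegetation group first, then the rest at random
    flat = np.arange(nrows * ncols)
    chosen = []
    for k in range(config.n_evg):
        chosen.append(int(r_plot.choice(flat[region.ravel() == k])))
    remaining = np.setdiff1d(flat, np.asarray(chosen))
    chosen += list(r_plot.choice(remaining, size=config.n_plots - config.n_evg, replace=False))
    plot_rows, plot_cols = np.unravel_index(np.asarray(chosen), config.shape)

    # disc-shaped disturbance patches, fire or insect/disease, one year
    # each; collapsed here (fire precedence, most recent year) so the
    # disturbed plots' structure can reflect the disturbance
    y0, y1 = config.disturbance_years
    layers = {}
    for _ in range(config.n_disturbance_patches):
        cy = r_dist.uniform(0, nrows)
        cx = r_dist.uniform(0, ncols)
        rad = config.patch_radius_px * r_dist.uniform(0.6, 1.4)
        year = int(r_dist.integers(y0, y1 + 1))
        dtype_code = DIST_FIRE if r_dist.random() < 0.5 else DIST_INSECT
        disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= rad ** 2
        layer = layers.setdefault(year, np.zeros(config.shape, dtype=int))
        layer[disc] = np.where(layer[disc] == DIST_FIRE, DIST_FIRE, dtype_code)
    annual = [(year, RasterBand(arr, -1, geo, crs)) for year, arr in sorted(layers.items())]
    if annual:
        dist_code_arr, dist_year_arr = collapse_disturbance(annual)
    else:
        dist_code_arr = np.zeros(config.shape, dtype=int)
        dist_year_arr = np.zeros(config.shape, dtype=int)

    # forest structure follows the biophysical gradients plus a
    # group-level offset: wetter and cooler sites carry denser, taller
    # stands, which is what makes the gradients informative predictors
    plot_region = region[plot_rows, plot_cols]
    # responses are keyed to the *mapped* surfaces (what both sides of
    # the imputation observe), standardised to the surface's scale
    zp_plot = (biophys["precip"][plot_rows, plot_cols] - 800.0) / 300.0
    zt_plot = (biophys["tmax"][plot_rows, plot_cols] - 18.0) / 5.0
    ze_plot = (elevation[plot_rows, plot_cols] - 1500.0) / 400.0
    # cover classes are ordinal, so a group shifts them by whole classes
    cover_offset = 10.0 * r_plot.integers(-2, 3, config.n_evg)
    height_offset = r_plot.uniform(-12, 18, config.n_evg)
    # Stands fall into discrete structure classes: the environment sets
    # which ordinal cover/height class a stand belongs to, and the
    # within-class spread is small relative to the class width.  The
    # class mean snaps to the class-representative value, mirroring how
    # both the mapped product and the plot classification discretise
    # into the same ordinal classes (and what makes the fitted forests'
    # out-of-bag errors small, as in the production runs this emulates).
    plot_dist = dist_code_arr[plot_rows, plot_cols]
    # disturbance thins the canopy: burned stands drop about two cover
    # classes, infested stands about one
    dist_cover_drop = np.where(plot_dist == DIST_FIRE, 20.0,
                               np.where(plot_dist == DIST_INSECT, 10.0, 0.0))
    cover_mu = (55.0 + 18.0 * zp_plot - 8.0 * zt_plot
                + cover_offset[plot_region] - dist_cover_drop)
    cover_mid = np.clip(np.round((cover_mu - 5.0) / 10.0) * 10.0 + 5.0, 15.0, 95.0)
    # overlap-corrected cover saturates below 100 %, so true plot cover
    # stays strictly under it
    cover_true = np.clip(cover_mid + r_plot.normal(0, 2.0, config.n_plots), 11.0, 97.0)
    # taller stands grow on wetter, lower sites; fire resets height
    height_mu = (20.0 + 8.0 * zp_plot - 6.0 * ze_plot
                 + height_offset[plot_region]
                 - np.where(plot_dist == DIST_FIRE, 8.0, 0.0))
    hvals = np.asarray(HEIGHT_BIN_VALUES, dtype=float)
    height_mid = hvals[np.argmin(np.abs(height_mu[:, None] - hvals[None, :]), axis=1)]
    height_true = np.clip(height_mid + r_plot.normal(0, 0.08 * height_mid + 0.5),
                          1.5, 80.0)
    plot_ids = np.arange(1001, 1001 + config.n_plots)

    # every pixel's generating plot: nearest plot within its vegetation group
    gen = np.empty(config.shape, dtype=np.int64)
    for k in range(config.n_evg):
        sel = plot_region == k
        tree = cKDTree(np.column_stack([plot_rows[sel], plot_cols[sel]]))
        pmask = region == k
        idx = tree.query(np.column_stack(np.nonzero(pmask)))[1]
        gen[pmask] = plot_ids[sel][idx]

    gidx = gen - plot_ids[0]  # plot ids are contiguous from 1001
    cover_band = np.clip(cover_true[gidx] + r_noise.normal(0, config.cover_noise_sd, config.shape)
                         if config.cover_noise_sd > 0 else cover_true[gidx], 2.0, 100.0)
    height_band = np.clip(height_true[gidx] + r_noise.normal(0, config.height_noise_sd, config.shape)
                          if config.height_noise_sd > 0 else height_true[gidx], 0.2, 95.0)

    def band(arr):
        return RasterBand(np.asarray(arr, dtype=float), -9999.0, geo, crs)

    stack = prepare_target_stack(
        cover_percent=band(cover_band), height_m=band(height_band),
        evg=RasterBand(evg.astype(int), -1, geo, crs),
        slope=band(slope), aspect=band(aspect), elevation=band(elevation),
        biophysical={k: band(v) for k, v in biophys.items()},
        annual_disturbance=annual)

    truth_frame = pd.DataFrame({
        "plot_id": plot_ids,
        "row": plot_rows, "col": plot_cols,
        "evg": np.asarray(evg_codes)[plot_region],
        "cover_pct_true": cover_true,
        "height_m_true": height_true,
        "cover_bin_true": bin_cover(cover_true),
        "height_bin_true": bin_height(height_true),
        "dist_code": stack.band("dist_code")[plot_rows, plot_cols],
        "dist_year": stack.band("dist_year")[plot_rows, plot_cols],
    })
    return stack, TruthMap(gen.astype(np.int64), truth_frame)


class GenerationError(RuntimeError):
    """Tree-list synthesis failed to land in the assigned bins."""


def _make_tree_list(rng, plot_id, cover_pct, height_m, dist_code, pool, config,
                    max_tries=50):
    """Tree records whose derived cover/height reproduce the plot values.

    Heights are rescaled so the nine-tree top-stratum average equals
    ``height_m`` exactly; expansion factors are solved so the summed
    crown load reproduces ``cover_pct`` through the overlap correction.
    The derived bins are re-checked through the real derivation code.
    """
    from . import plots as plots_mod

    unit_area = SQ_M_PER_ACRE if config.tpa_unit == "per_acre" else SQ_M_PER_HECTARE
    target_load = -np.log(1.0 - cover_pct / 100.0) * unit_area
    for _ in range(max_tries):
        n_live = max(9, int(rng.poisson(config.mean_live_trees)))
        heights = np.clip(rng.normal(height_m, 0.08 * height_m + 0.3, n_live), 0.5, None)
        trees = [plots_mod.TreeRecord(1, 0, 0, 1.0, float(h), 1.0, 1.0) for h in heights]
        top = plots_mod.top_stratum_height(trees)
        heights = heights * (height_m / top)

        radii = np.clip(rng.normal(2.5, 0.5, n_live), 0.8, 6.0)
        weights = rng.dirichlet(np.full(n_live, 4.0))
        tpa = target_load * weights / (np.pi * radii ** 2)
        diam = np.clip(heights * rng.normal(1.9, 0.15, n_live), 2.0, None)

        n_species = int(rng.integers(2, min(4, len(pool)) + 1))
        sp_choices = rng.choice(pool, size=n_species, replace=False)
        species = rng.choice(sp_choices, size=n_live)

        rows = [
            {"PLT_CN": plot_id, "STATUSCD": 1, "STANDING_DEAD_CD": 0,
             "SPCD": int(species[i]), "DIA": float(diam[i]), "HT": float(heights[i]),
             "TPA_UNADJ": float(tpa[i]), "CROWN_RADIUS": float(radii[i])}
            for i in range(n_live)
        ]
        extra = {DIST_FIRE: config.fire_dead_extra, DIST_INSECT: config.insect_dead_extra}.get(int(dist_code), 0.0)
        n_dead = int(rng.poisson(config.dead_base_mean + extra))
        for _ in range(n_dead):
            rows.append({"PLT_CN": plot_id, "STATUSCD": 2, "STANDING_DEAD_CD": 1,
                         "SPCD": int(rng.choice(sp_choices)),
                         "DIA": float(rng.uniform(8, 50)), "HT": float(rng.uniform(3, height_m + 5)),
                         "TPA_UNADJ": float(rng.uniform(1, 20)), "CROWN_RADIUS": np.nan})

        frame = pd.DataFrame(rows)
        trees = plots_mod.trees_from_frame(frame)
        ok_cover = bin_cover(max(plots_mod.canopy_cover(trees, config.tpa_unit), 10.0)) == bin_cover(cover_pct)
        ok_height = bin_height(plots_mod.top_stratum_height(trees)) == bin_height(height_m)
        if ok_cover and ok_height:
            return frame
    raise GenerationError(
        f"plot {plot_id}: tree list failed to reproduce bins after {max_tries} tries "
        f"(cover {cover_pct:.1f}%, height {height_m:.1f} m)")


def generate_plots(config: SynthConfig, stack: TargetStack, truth: TruthMap):
    """Plot and tree tables for the reference network plus validation plots.

    Reference plots (condition count 1) sit at their true pixels with
    tree lists reproducing their assigned bins; validation plots
    (condition count 2) sit at fresh random pixels and carry attributes
    of their pixel's generating plot perturbed by the validation noise,
    emulating independently remeasured, heterogeneous plots.
    """
    ss = np.random.SeedSequence([int(config.rng_seed), 13])
    r_tree, r_val = [np.random.default_rng(s) for s in ss.spawn(2)]
    pools = species_pools()
    geo = stack.geometry

    plot_rows, tree_frames = [], []

    def location(row, col):
        x, y = geo.pixel_center(row, col)
        from .raster import to_geographic
        return to_geographic(stack.crs, x, y)

    for t in truth.plot_truth.itertuples():
        lat, lon = location(t.row, t.col)
        tree_frames.append(_make_tree_list(
            r_tree, int(t.plot_id), float(t.cover_pct_true), float(t.height_m_true),
            int(t.dist_code), pools[int(t.evg)], config))
        plot_rows.append({
            "PLT_CN": int(t.plot_id), "LAT": float(lat), "LON": float(lon),
            "SLOPE": float(stack.band("slope")[t.row, t.col]),
            "ASPECT": float(stack.band("aspect")[t.row, t.col]),
            "ELEV": float(stack.band("elevation")[t.row, t.col]),
            "EVG": int(t.evg), "CONDITION_COUNT": 1,
            "DSTRBCD1": int(t.dist_code) or np.nan,
            "DSTRBYR1": int(t.dist_year) or np.nan,
            "DSTRBCD2": np.nan, "DSTRBYR2": np.nan,
            "DSTRBCD3": np.nan, "DSTRBYR3": np.nan,
        })

    # held-out multi-condition validation plots
    nrows, ncols = stack.shape
    truth_by_id = truth.plot_truth.set_index("plot_id")
    next_id = int(truth.plot_truth["plot_id"].max()) + 1
    forest = np.column_stack(np.nonzero(stack.mask))
    pick = r_val.choice(forest.shape[0], size=min(config.n_validation_plots, forest.shape[0]),
                        replace=False)
    for k, (row, col) in enumerate(forest[pick]):
        gen_id = int(truth.gen_plot_id[row, col])
        g = truth_by_id.loc[gen_id]
        cover = float(np.clip(g.cover_pct_true + r_val.normal(0, config.validation_noise_sd), 11, 97))
        height = float(np.clip(g.height_m_true + r_val.normal(0, config.validation_noise_sd / 2), 1.5, 90))
        pid = next_id + k
        lat, lon = location(row, col)
        tree_frames.append(_make_tree_list(
            r_val, pid, cover, height, int(g.dist_code), pools[int(g.evg)], config))
        plot_rows.append({
            "PLT_CN": pid, "LAT": float(lat), "LON": float(lon),
            "SLOPE": float(stack.band("slope")[row, col]),
            "ASPECT": float(stack.band("aspect")[row, col]),
            "ELEV": float(stack.band("elevation")[row, col]),
            "EVG": int(g.evg), "CONDITION_COUNT": 2,
            "DSTRBCD1": int(g.dist_code) or np.nan,
            "DSTRBYR1": int(g.dist_year) or np.nan,
            "DSTRBCD2": np.nan, "DSTRBYR2": np.nan,
            "DSTRBCD3": np.nan, "DSTRBYR3": np.nan,
        })

    plot_table = pd.DataFrame(plot_rows)
    tree_table = pd.concat(tree_frames, ignore_index=True)
    return plot_table, tree_table


def generate(config: SynthConfig | None = None) -> SynthResult:
    """Full synthetic dataset: stack, truth, plot table, tree table."""
    config = config or SynthConfig()
    stack, truth = generate_landscape(config)
    plot_table, tree_table = generate_plots(config, stack, truth)
    return SynthResult(stack, truth, plot_table, tree_table, config)
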