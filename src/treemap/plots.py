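"""Plot-level attribute derivation from tree-level inventory records.

Reference data for the imputation are forest-inventory plots.  Each
plot carries a tree list (status, species, diameter, height, expansion
factor, crown radius) from which we derive the attributes that must
exist on both sides of the imputation: the canopy-cover bin, the
canopy-height bin, the disturbance code/year, the standing-dead count
used in the disturbance analysis, and the two species with the largest
basal area used in validation.

Column contract (CSV headers mirror the FIA database where a field
exists there):

tree table
    PLT_CN, STATUSCD (1=live, 2=dead, 3=cut), STANDING_DEAD_CD (0/1),
    SPCD, DIA (cm), HT (m), TPA_UNADJ (per acre unless the config says
    per hectare), CROWN_RADIUS (m; supplied by allometry upstream or by
    the synthetic generator)

plot table
    PLT_CN, LAT, LON (decimal degrees), SLOPE (deg), ASPECT (deg),
    ELEV (m), EVG, CONDITION_COUNT, DSTRBCD1..3, DSTRBYR1..3
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import from_geographic
from .target_prep import (
    BIOPHYSICAL_BANDS,
    DIST_FIRE,
    DIST_INSECT,
    DIST_NONE,
    DIST_YEAR_SENTINEL,
    InvalidRecordError,
    MIN_FOREST_COVER_PCT,
    NonForestError,
    TargetStack,
    bin_cover,
    bin_height,
)

STATUS_LIVE = 1
STATUS_DEAD = 2
STATUS_CUT = 3

SQ_M_PER_ACRE = 4046.8564224
SQ_M_PER_HECTARE = 10000.0

TREE_COLUMNS = ["PLT_CN", "STATUSCD", "STANDING_DEAD_CD", "SPCD", "DIA", "HT",
                "TPA_UNADJ", "CROWN_RADIUS"]
PLOT_COLUMNS = ["PLT_CN", "LAT", "LON", "SLOPE", "ASPECT", "ELEV", "EVG",
                "CONDITION_COUNT",
                "DSTRBCD1", "DSTRBCD2", "DSTRBCD3",
                "DSTRBYR1", "DSTRBYR2", "DSTRBYR3"]


class UndefinedHeightError(ValueError):
    """No live tree with a height; the plot has no top-stratum height."""


@dataclass
class TreeRecord:
    """One measured tree."""

    status_code: int
    standing_dead_flag: int
    species_code: int
    diameter_cm: float
    height_m: float
    tpa: float
    crown_radius_m: float | None = None

    def __post_init__(self):
        if self.standing_dead_flag == 1 and self.status_code != STATUS_DEAD:
            raise InvalidRecordError("standing-dead flag on a non-dead tree")
        if self.status_code == STATUS_LIVE and not self.diameter_cm > 0:
            raise InvalidRecordError("live tree with non-positive diameter")
        if self.status_code == STATUS_LIVE and not self.tpa > 0:
            raise InvalidRecordError("live tree with non-positive expansion factor")

    @property
    def is_live(self):
        return self.status_code == STATUS_LIVE


def trees_from_frame(frame: pd.DataFrame) -> list[TreeRecord]:
    return [
        TreeRecord(int(r.STATUSCD), int(r.STANDING_DEAD_CD), int(r.SPCD),
                   float(r.DIA), float(r.HT), float(r.TPA_UNADJ),
                   None if pd.isna(r.CROWN_RADIUS) else float(r.CROWN_RADIUS))
        for r in frame.itertuples()
    ]


def count_standing_dead(trees) -> int:
    """Number of standing-dead stems (flag validated against status)."""
    n = 0
    for t in trees:
        if t.standing_dead_flag == 1:
            if t.status_code != STATUS_DEAD:
                raise InvalidRecordError("standing-dead flag on a non-dead tree")
            n += 1
    return n


def assign_plot_disturbance(codes, years):
    """Most recent disturbance with fire preferred over insect/disease.

    ``codes``/``years`` are the up-to-three disturbance slots of an
    inventory plot, already filtered to fire / insect-disease causes.
    Identical precedence logic to the raster-side collapse: any fire at
    all wins, carrying the most recent *fire* year.
    """
    pairs = []
    for c, y in zip(codes, years):
        c_missing = c is None or (isinstance(c, float) and math.isnan(c)) or c == DIST_NONE
        y_missing = y is None or (isinstance(y, float) and math.isnan(y)) or y == DIST_YEAR_SENTINEL
        if c_missing and y_missing:
            continue
        if c_missing or y_missing:
            raise InvalidRecordError("disturbance slot with code/year half missing")
        c = int(c)
        if c not in (DIST_FIRE, DIST_INSECT):
            raise InvalidRecordError(f"unexpected disturbance code {c}")
        pairs.append((c, int(y)))
    fire_years = [y for c, y in pairs if c == DIST_FIRE]
    insect_years = [y for c, y in pairs if c == DIST_INSECT]
    if fire_years:
        return DIST_FIRE, max(fire_years)
    if insect_years:
        return DIST_INSECT, max(insect_years)
    return DIST_NONE, DIST_YEAR_SENTINEL


def top_stratum_height(trees) -> float:
    """Mean height of the nine trees centred on the 70th-percentile tree.

    Live-tree heights are sorted ascending; the anchor is the tree at
    1-based rank ceil(0.70 n); the averaging window spans the nine ranks
    centred there, clipped to the list bounds; with fewer than nine
    trees all are averaged.
    """
    heights = sorted(t.height_m for t in trees if t.is_live and t.height_m is not None)
    n = len(heights)
    if n == 0:
        raise UndefinedHeightError("no live tree with height")
    if n < 9:
        return float(np.mean(heights))
    rank = math.ceil(0.70 * n)  # 1-based
    lo = max(1, rank - 4)
    hi = min(n, rank + 4)
    return float(np.mean(heights[lo - 1:hi]))


def canopy_cover(trees, tpa_unit: str = "per_acre") -> float:
    """Percent canopy cover with a random-placement overlap correction.

    The uncorrected crown load is the summed crown area per unit ground
    area, lambda = sum(pi r_i^2 tpa_i) / unit_area; assuming crowns fall
    independently, the covered fraction is 1 - exp(-lambda), so cover
    saturates below 100 % however dense the stand.
    """
    unit_area = {"per_acre": SQ_M_PER_ACRE, "per_hectare": SQ_M_PER_HECTARE}[tpa_unit]
    load = 0.0
    for t in trees:
        if not t.is_live:
            continue
        if t.crown_radius_m is None:
            raise InvalidRecordError("live tree without crown radius")
        load += math.pi * t.crown_radius_m ** 2 * t.tpa
    return 100.0 * (1.0 - math.exp(-load / unit_area))


def top_two_species(trees):
    """Two species codes with the largest live basal area.

    Basal area per species is sum of pi (d/2)^2 tpa over live trees.
    Ties break toward the ascending species code; a monospecific plot
    returns (species, None).
    """
    ba: dict[int, float] = {}
    for t in trees:
        if not t.is_live:
            continue
        ba[t.species_code] = ba.get(t.species_code, 0.0) + math.pi * (t.diameter_cm / 2.0) ** 2 * t.tpa
    if not ba:
        return None, None
    ranked = sorted(ba.items(), key=lambda kv: (-kv[1], kv[0]))
    first = ranked[0][0]
    second = ranked[1][0] if len(ranked) > 1 else None
    return first, second


REFERENCE_COLUMNS = (
    ["plot_id", "lat", "lon", "slope", "aspect", "elevation"]
    + list(BIOPHYSICAL_BANDS)
    + ["cover_bin", "height_bin", "evg", "dist_code", "dist_year",
       "standing_dead_count", "top_sp1", "top_sp2",
       "cover_pct", "height_m", "condition_count"]
)


@dataclass
class ReferenceTables:
    """Output of :func:`build_reference_table`.

    ``reference``: single-condition, forested plots, imputation-ready.
    ``validation``: multi-condition plots with the same derived columns,
    held out for footprint validation.  ``dropped`` counts exclusions.
    """

    reference: pd.DataFrame
    validation: pd.DataFrame
    dropped: dict


def build_reference_table(plot_table: pd.DataFrame, tree_table: pd.DataFrame,
                          target_stack: TargetStack, tpa_unit: str = "per_acre") -> ReferenceTables:
    """Join plot and tree tables into imputation-ready reference rows.

    Derives cover/height bins, disturbance, standing-dead count and
    top-two species per plot; samples the six biophysical bands at the
    plot location; drops multi-condition plots (kept as the validation
    set), plots under 10 % derived cover, plots without live trees and
    plots outside the raster extent (counted in ``dropped``).
    """
    trees_by_plot = {pid: grp for pid, grp in tree_table.groupby("PLT_CN")}
    geo = target_stack.geometry
    dropped = {"multi_condition": 0, "below_min_cover": 0, "outside_extent": 0,
               "no_live_trees": 0}
    ref_rows, val_rows = [], []

    for prow in plot_table.itertuples():
        pid = prow.PLT_CN
        tgrp = trees_by_plot.get(pid)
        trees = trees_from_frame(tgrp) if tgrp is not None else []
        x, y = from_geographic(target_stack.crs, prow.LAT, prow.LON)
        if not geo.contains(x, y):
            dropped["outside_extent"] += 1
            continue
        row, col = geo.index_of(x, y)

        try:
            height = top_stratum_height(trees)
        except UndefinedHeightError:
            dropped["no_live_trees"] += 1
            continue
        cover_pct = canopy_cover(trees, tpa_unit)
        multi = int(prow.CONDITION_COUNT) > 1
        if cover_pct < MIN_FOREST_COVER_PCT and not multi:
            dropped["below_min_cover"] += 1
            continue
        code, year = assign_plot_disturbance(
            [getattr(prow, f"DSTRBCD{i}", None) for i in (1, 2, 3)],
            [getattr(prow, f"DSTRBYR{i}", None) for i in (1, 2, 3)],
        )
        sp1, sp2 = top_two_species(trees)
        rec = {
            "plot_id": pid,
            "lat": float(prow.LAT),
            "lon": float(prow.LON),
            "slope": float(prow.SLOPE),
            "aspect": float(prow.ASPECT),
            "elevation": float(prow.ELEV),
            **{b: float(target_stack.band(b)[int(row), int(col)]) for b in BIOPHYSICAL_BANDS},
            "cover_bin": bin_cover(cover_pct) if cover_pct >= MIN_FOREST_COVER_PCT else 0,
            "height_bin": bin_height(height),
            "evg": int(prow.EVG),
            "dist_code": code,
            "dist_year": year,
            "standing_dead_count": count_standing_dead(trees),
            "top_sp1": sp1,
            "top_sp2": sp2,
            "cover_pct": cover_pct,
            "height_m": height,
            "condition_count": int(prow.CONDITION_COUNT),
        }
        if multi:
            dropped["multi_condition"] += 1
            val_rows.append(rec)
        else:
            ref_rows.append(rec)

    reference = pd.DataFrame(ref_rows, columns=REFERENCE_COLUMNS)
    validation = pd.DataFrame(val_rows, columns=REFERENCE_COLUMNS)
    return ReferenceTables(reference, validation, dropped)
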