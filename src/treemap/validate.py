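"""Accuracy assessment of an imputed plot-identifier map.

Three complementary comparisons:

1. pixel-to-pixel confusion matrices between the attribute surfaces
   carried by the imputed plots and the target surfaces, summarised by
   overall, user's (diagonal / row total: probability the mapped class
   is right) and producer's (diagonal / column total: probability a
   ground class was mapped) accuracies;
2. plot-footprint agreement: an inventory plot's splayed footprint is a
   40.25 m-radius disc spanning several 30 m pixels; we ask whether any
   footprint pixel matches the plot's cover/height bin, whether the
   equal-weight mean of the footprint pixels' cover (height) values is
   within 10 percentage points (5 m) of the plot value, and whether any
   footprint pixel's plot shares one of the validation plot's two
   highest-basal-area species;
3. a two-sample Kolmogorov-Smirnov comparison of standing-dead-tree
   counts between disturbed and undisturbed plots, the analysis that
   motivates carrying disturbance code/year as predictors.

Rows of every confusion matrix are the imputed classes, columns the
target classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .raster import from_geographic
from .target_prep import DIST_FIRE, DIST_INSECT, DIST_NONE, TargetStack

#: radius (m) of the disc spanned by the four-subplot inventory design:
#: 7.3 m subplots whose outer centres sit 36.6 m from the plot centre
FOOTPRINT_RADIUS_M = 40.25

COVER_TOLERANCE_PCT = 10.0
HEIGHT_TOLERANCE_M = 5.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (prints 43.75 -> 43.8, unlike banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class VocabularyError(ValueError):
    """A raster class code outside the declared class vocabulary."""


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = imputed class, columns = target class."""

    labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(list(self.labels), self.counts.T.copy())

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        frame.index.name = "imputed"
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        labels = []
        for c in frame.columns:
            try:
                labels.append(int(c))
            except ValueError:
                labels.append(c)
        return cls(labels, frame.to_numpy(dtype=np.int64))


def confusion(imputed_attr, target_attr, mask, labels=None) -> ConfusionMatrix:
    """Pixel-wise confusion counts within ``mask``.

    When ``labels`` is given it is the closed class vocabulary and any
    value outside it raises :class:`VocabularyError`; otherwise the
    vocabulary is the sorted union of observed values.
    """
    a = np.asarray(imputed_attr)[np.asarray(mask, dtype=bool)]
    b = np.asarray(target_attr)[np.asarray(mask, dtype=bool)]
    if labels is None:
        labels = sorted(set(np.unique(a)) | set(np.unique(b)))
    lab_arr = np.asarray(labels)
    ia = np.searchsorted(lab_arr, a)
    ib = np.searchsorted(lab_arr, b)
    bad_a = (ia >= lab_arr.size) | (lab_arr[np.minimum(ia, lab_arr.size - 1)] != a)
    bad_b = (ib >= lab_arr.size) | (lab_arr[np.minimum(ib, lab_arr.size - 1)] != b)
    if bad_a.any() or bad_b.any():
        offending = np.unique(np.concatenate([a[bad_a], b[bad_b]]))
        raise VocabularyError(f"class codes outside vocabulary: {offending.tolist()}")
    k = lab_arr.size
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ia, ib), 1)
    return ConfusionMatrix([l.item() if hasattr(l, "item") else l for l in lab_arr], counts)


@dataclass
class AccuracyMetrics:
    overall: float
    users: np.ndarray      # per imputed class; NaN where the row is empty
    producers: np.ndarray  # per target class; NaN where the column is empty
    labels: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class": self.labels, "users_accuracy": self.users,
                             "producers_accuracy": self.producers})


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyMetrics:
    """Overall, user's and producer's accuracy of a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm.counts).astype(float)
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        users = np.where(rows > 0, diag / rows, np.nan)
        producers = np.where(cols > 0, diag / cols, np.nan)
    overall = float(diag.sum() / cm.total)
    return AccuracyMetrics(overall, users, producers, list(cm.labels))


def footprint_pixels(plot_x: float, plot_y: float, geometry,
                     radius: float = FOOTPRINT_RADIUS_M):
    """Pixels whose centroid lies within ``radius`` of the plot centre.

    Coordinates are planar (projected CRS); distance is Euclidean.
    Returns (rows, cols) clipped to the raster extent; empty when the
    plot lies outside it.
    """
    size = geometry.pixel_size
    r0, c0 = geometry.index_of(plot_x, plot_y)
    halo = int(np.ceil(radius / size)) + 1
    rr = np.arange(max(0, r0 - halo), min(geometry.nrows, r0 + halo + 1))
    cc = np.arange(max(0, c0 - halo), min(geometry.ncols, c0 + halo + 1))
    if rr.size == 0 or cc.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    R, C = np.meshgrid(rr, cc, indexing="ij")
    x, y = geometry.pixel_center(R, C)
    within = (x - plot_x) ** 2 + (y - plot_y) ** 2 <= radius ** 2
    return R[within], C[within]


FOOTPRINT_FLAGS = ("cover_any_match", "height_any_match",
                   "cover_weighted_within_10", "height_weighted_within_5m",
                   "species_top2_match")


@dataclass
class FootprintSummary:
    per_plot: pd.DataFrame
    rates: dict          # flag -> percent (one decimal, half-up)
    counts: dict         # flag -> matched-plot count
    n_forested: int      # plots with >= 1 forested footprint pixel (denominator)
    n_obtained: int      # validation plots supplied


def footprint_agreement(validation: pd.DataFrame, stack: TargetStack,
                        imputed_map=None, source: str = "imputed",
                        radius: float = FOOTPRINT_RADIUS_M) -> FootprintSummary:
    """Footprint agreement flags and summary rates for validation plots.

    ``source='imputed'`` looks attributes up through the imputed plot of
    each footprint pixel; ``source='target'`` reads the target bands
    directly (species then unavailable).  Plots without a single
    forested footprint pixel are excluded from every denominator but
    counted in ``n_obtained``.
    """
    if source not in ("imputed", "target"):
        raise ValueError("source must be 'imputed' or 'target'")
    if source == "imputed":
        attrs = imputed_map.attributes
        lut = attrs.set_index("plot_id")
        cover_of = lut["cover_bin"].to_dict()
        height_of = lut["height_bin"].to_dict()
        sp1_of = lut["top_sp1"].to_dict()
        sp2_of = lut["top_sp2"].to_dict()

    rows_out = []
    for prow in validation.itertuples():
        x, y = from_geographic(stack.crs, prow.lat, prow.lon)
        rr, cc = footprint_pixels(x, y, stack.geometry, radius)
        if rr.size:
            keep = stack.mask[rr, cc]
            rr, cc = rr[keep], cc[keep]
        n_pix = int(rr.size)
        rec = {"plot_id": prow.plot_id, "n_pixels": n_pix}
        if n_pix == 0:
            rec.update({f: None for f in FOOTPRINT_FLAGS})
            rows_out.append(rec)
            continue
        if source == "imputed":
            pix_ids = imputed_map.plot_id[rr, cc]
            pix_cover = np.array([cover_of[i] for i in pix_ids], dtype=float)
            pix_height = np.array([height_of[i] for i in pix_ids], dtype=float)
        else:
            pix_cover = stack.band("cover_bin")[rr, cc].astype(float)
            pix_height = stack.band("height_bin")[rr, cc].astype(float)
        rec["cover_any_match"] = bool((pix_cover == prow.cover_bin).any())
        rec["height_any_match"] = bool((pix_height == prow.height_bin).any())
        rec["cover_weighted_within_10"] = bool(
            abs(pix_cover.mean() - prow.cover_pct) <= COVER_TOLERANCE_PCT)
        rec["height_weighted_within_5m"] = bool(
            abs(pix_height.mean() - prow.height_m) <= HEIGHT_TOLERANCE_M)
        if source == "imputed":
            plot_sp = {s for s in (prow.top_sp1, prow.top_sp2) if s is not None and not pd.isna(s)}
            match = False
            for i in pix_ids:
                pix_sp = {s for s in (sp1_of[i], sp2_of[i]) if s is not None and not pd.isna(s)}
                if plot_sp & pix_sp:
                    match = True
                    break
            rec["species_top2_match"] = match
        else:
            rec["species_top2_match"] = None
        rows_out.append(rec)

    per_plot = pd.DataFrame(rows_out)
    forested = per_plot[per_plot["n_pixels"] > 0]
    n_forested = len(forested)
    rates, counts = {}, {}
    for flag in FOOTPRINT_FLAGS:
        col = forested[flag]
        if col.isna().all():
            rates[flag] = None
            counts[flag] = None
            continue
        counts[flag] = int(col.fillna(False).sum())
        rates[flag] = round_half_up(100.0 * counts[flag] / n_forested, 1) if n_forested else None
    return FootprintSummary(per_plot, rates, counts, n_forested, len(validation))


@dataclass
class KsResult:
    d: float
    p_value: float
    n_a: int
    n_b: int


def ks_two_sample(sample_a, sample_b) -> KsResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF distance evaluated exhaustively at every
    observed point; the p-value comes from the asymptotic Kolmogorov
    distribution at effective size n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    en = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(en) * d))
    return KsResult(d, min(max(p, np.finfo(float).tiny), 1.0), int(a.size), int(b.size))


def dead_tree_disturbance_analysis(reference: pd.DataFrame) -> pd.DataFrame:
    """Do disturbed plots carry more standing-dead trees?

    Compares standing-dead counts of burned plots and of insect/disease
    plots against undisturbed plots with the KS test; a comparison with
    an empty group is reported as skipped.
    """
    groups = {
        "undisturbed": reference.loc[reference["dist_code"] == DIST_NONE, "standing_dead_count"],
        "fire": reference.loc[reference["dist_code"] == DIST_FIRE, "standing_dead_count"],
        "insect_disease": reference.loc[reference["dist_code"] == DIST_INSECT, "standing_dead_count"],
    }
    rows = []
    for name in ("fire", "insect_disease"):
        row = {"comparison": f"{name}_vs_undisturbed",
               "n_disturbed": len(groups[name]), "n_undisturbed": len(groups["undisturbed"])}
        if len(groups[name]) == 0 or len(groups["undisturbed"]) == 0:
            row.update({"d": None, "p_value": None, "status": "skipped: empty group"})
        else:
            res = ks_two_sample(groups[name], groups["undisturbed"])
            row.update({"d": res.d, "p_value": res.p_value, "status": "ok"})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published CONUS-2014 benchmark tables (shipped inputs)

_DATA = Path(__file__).parent / "data" / "conus2014"


def published_confusion(which: str) -> ConfusionMatrix:
    """The published CONUS-scale agreement matrix for 2014.

    ``which`` is ``cover``, ``height`` or ``disturbance``.
    """
    return ConfusionMatrix.from_csv(_DATA / f"{which}_confusion.csv")


def published_footprint_counts() -> pd.DataFrame:
    """Published footprint-validation match counts and denominators."""
    return pd.read_csv(_DATA / "footprint_summary.csv")
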