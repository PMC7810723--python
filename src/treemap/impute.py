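"""Random-forest nearest-neighbour imputation by terminal-node co-occurrence.

The engine fits, per response variable (cover bin, height bin,
vegetation group), an ensemble of classification trees on the reference
plots; a target pixel is then dropped down every tree of every
ensemble, and each reference plot is credited once for every tree in
whose terminal node it lands together with the pixel.  The plot with
the highest total co-occurrence count is imputed to the pixel, ties
split uniformly at random under the run seed.  The result is a raster
of plot identifiers, not of predicted attribute values: the attributes
travel with the plot.

Tree construction follows the classical CART recipe with the choices
that matter spelled out:

* bootstrap = 66 % of the reference plots drawn *without* replacement
  per tree; the remaining plots provide the out-of-bag error;
* at each node, ``floor(sqrt(k))`` of the k candidate variables are
  drawn at random for assessment; the Gini-impurity-minimising binary
  split wins, ties broken by ascending variable index;
* categorical variables (vegetation group, disturbance code) split on
  category subsets found greedily by ordering categories on their
  node-modal-class probability; numeric thresholds are midpoints of
  adjacent observed values;
* a split is accepted only if both children keep at least ``min_bucket``
  plots and impurity strictly decreases.

With ``responses_as_split_candidates`` (the default) the candidate
variables of every tree are the predictors plus *all* response bands,
the tree's own label included.  A tree that draws its own response at a
node splits on it with maximal gain, which drives terminal nodes toward
response purity; at prediction time the target pixel's observed
cover/height/group surfaces then steer it into terminal nodes of
matching plots.  This is what makes imputed attribute surfaces agree
closely with the target surfaces, and it deflates the out-of-bag error,
which inherits label information through the routing — both hallmarks
of the production runs this engine re-implements.  Setting the flag
false restricts candidates to the predictors, the classical
formulation, whose out-of-bag error is an honest generalisation
estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import GridGeometry, RasterBand, check_aligned, read_ascii_grid, write_ascii_grid
from .target_prep import (
    CATEGORICAL_VARS,
    PREDICTOR_BANDS,
    RESPONSE_BANDS,
    TargetStack,
    UnresolvedClassError,
)

log = logging.getLogger(__name__)

NODATA_ID = -9999


class ZoneSkippedError(ValueError):
    """A zone has no reference plot at all; it cannot be imputed."""


class TooManyClassesError(ValueError):
    """A zonal run exceeds the configured categorical-class budget."""


@dataclass
class ImputationConfig:
    """Knobs of the imputation engine (defaults are the production recipe)."""

    trees_per_response: int = 83
    responses: tuple = RESPONSE_BANDS
    predictors: tuple = PREDICTOR_BANDS
    bootstrap_fraction: float = 0.66
    min_bucket: int = 5
    responses_as_split_candidates: bool = True
    rng_seed: int = 0
    max_classes_per_run: int = 32

    def __post_init__(self):
        if self.trees_per_response < 1:
            raise ValueError("trees_per_response must be >= 1")
        if not 0 < self.bootstrap_fraction < 1:
            raise ValueError("bootstrap_fraction must be in (0, 1)")
        if self.min_bucket < 2:
            raise ValueError("min_bucket must be >= 2")

    def feature_names(self, response: str) -> list[str]:
        feats = list(self.predictors)
        if self.responses_as_split_candidates:
            feats += list(self.responses)
        return feats


class DecisionTree:
    """One grown classification tree with its leaf membership index.

    Nodes live in parallel arrays; ``leaf_members`` maps a leaf node id
    to the *global* indices of the in-bag reference plots that ended in
    that leaf, which is exactly the set a co-occurring pixel votes for.
    """

    __slots__ = ("feature", "threshold", "left_cats", "right_cats", "left",
                 "right", "n_node", "leaf_majority", "leaf_members", "inbag")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left_cats: list = []
        self.right_cats: list = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.n_node: list[int] = []
        self.leaf_majority: dict[int, int] = {}
        self.leaf_members: dict[int, np.ndarray] = {}
        self.inbag: np.ndarray | None = None

    def _new_node(self, n: int) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left_cats.append(None)
        self.right_cats.append(None)
        self.left.append(-1)
        self.right.append(-1)
        self.n_node.append(n)
        return len(self.feature) - 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_members)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id for every row of ``X`` (vectorised routing).

        A categorical level unseen at a node routes to the child with
        more in-bag observations.
        """
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=np.int64)
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            nid, idx = stack.pop()
            if idx.size == 0:
                continue
            f = self.feature[nid]
            if f < 0:
                out[idx] = nid
                continue
            vals = X[idx, f]
            lcats = self.left_cats[nid]
            if lcats is not None:
                go_left = np.isin(vals, lcats)
                known = go_left | np.isin(vals, self.right_cats[nid])
                if not known.all():
                    bigger_left = self.n_node[self.left[nid]] >= self.n_node[self.right[nid]]
                    go_left = np.where(known, go_left, bigger_left)
            else:
                go_left = vals <= self.threshold[nid]
            stack.append((self.left[nid], idx[go_left]))
            stack.append((self.right[nid], idx[~go_left]))
        return out


def _gini_children(left_counts, right_counts):
    """Weighted Gini impurity of a candidate split (vectorised over splits)."""
    nl = left_counts.sum(axis=-1)
    nr = right_counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gl = 1.0 - (left_counts ** 2).sum(axis=-1) / nl ** 2
        gr = 1.0 - (right_counts ** 2).sum(axis=-1) / nr ** 2
    return (nl * gl + nr * gr) / (nl + nr)


def _grow_tree(X, y, n_classes, var_is_cat, min_bucket, mtry, rng,
               inbag_global) -> DecisionTree:
    """Grow one tree on the in-bag rows (X, y are already subset)."""
    tree = DecisionTree()
    n, n_vars = X.shape

    def node_gini(counts):
        tot = counts.sum()
        return 1.0 - ((counts / tot) ** 2).sum()

    def make_leaf(nid, idx, counts):
        order = np.argsort(-counts, kind="stable")  # majority, ties -> low label
        tree.leaf_majority[nid] = int(order[0])
        tree.leaf_members[nid] = inbag_global[idx]

    def best_split_numeric(vals, labels, counts):
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        sy = labels[order]
        m = sv.size
        cum = np.zeros((m, n_classes))
        cum[np.arange(m), sy] = 1.0
        cum = np.cumsum(cum, axis=0)
        pos = np.arange(m - 1)
        valid = (sv[:-1] < sv[1:]) & (pos + 1 >= min_bucket) & (m - pos - 1 >= min_bucket)
        if not valid.any():
            return None
        left = cum[:-1][valid]
        right = counts - left
        score = _gini_children(left, right)
        best = int(np.argmin(score))
        i = pos[valid][best]
        thr = 0.5 * (sv[i] + sv[i + 1])
        return float(score[best]), ("num", thr)

    def best_split_categorical(vals, labels, counts):
        # greedy subset search: order categories by their probability of
        # one response class, scan prefix splits; do this for every
        # class present and keep the best (deterministic tie-breaks)
        cats = np.unique(vals)
        if cats.size < 2:
            return None
        cat_counts = np.zeros((cats.size, n_classes))
        for ci, c in enumerate(cats):
            sel = vals == c
            cat_counts[ci] = np.bincount(labels[sel], minlength=n_classes)
        cat_totals = cat_counts.sum(axis=1)
        best_score, best_sets = np.inf, None
        for cls in np.flatnonzero(counts):
            p_cls = cat_counts[:, cls] / cat_totals
            order = np.lexsort((cats, p_cls))  # by class probability, tie by code
            cum = np.cumsum(cat_counts[order], axis=0)
            left = cum[:-1]
            right = counts - left
            nl = left.sum(axis=1)
            nr = right.sum(axis=1)
            valid = (nl >= min_bucket) & (nr >= min_bucket)
            if not valid.any():
                continue
            score = _gini_children(left, right)
            score = np.where(valid, score, np.inf)
            k = int(np.argmin(score))
            if score[k] < best_score - 1e-12:
                best_score = float(score[k])
                best_sets = (np.sort(cats[order][:k + 1]), np.sort(cats[order][k + 1:]))
        if best_sets is None:
            return None
        return best_score, ("cat", best_sets)

    def grow(idx):
        labels = y[idx]
        counts = np.bincount(labels, minlength=n_classes).astype(float)
        nid = tree._new_node(idx.size)
        parent_gini = node_gini(counts)
        if idx.size < 2 * min_bucket or parent_gini <= 0.0:
            make_leaf(nid, idx, counts)
            return nid
        k = min(mtry, n_vars)
        cand = np.sort(rng.choice(n_vars, size=k, replace=False))
        best_score, best_var, best_desc = np.inf, -1, None
        for v in cand:  # ascending order: gain ties break to the lowest index
            vals = X[idx, v]
            res = (best_split_categorical if var_is_cat[v] else best_split_numeric)(vals, labels, counts)
            if res is None:
                continue
            score, desc = res
            if score < best_score - 1e-12:
                best_score, best_var, best_desc = score, v, desc
        if best_var < 0 or best_score >= parent_gini - 1e-12:
            make_leaf(nid, idx, counts)
            return nid
        kind, payload = best_desc
        vals = X[idx, best_var]
        if kind == "num":
            go_left = vals <= payload
            tree.threshold[nid] = payload
        else:
            left_set, right_set = payload
            go_left = np.isin(vals, left_set)
            tree.left_cats[nid] = left_set.astype(float)
            tree.right_cats[nid] = right_set.astype(float)
        tree.feature[nid] = int(best_var)
        tree.left[nid] = grow(idx[go_left])
        tree.right[nid] = grow(idx[~go_left])
        return nid

    grow(np.arange(n))
    return tree


@dataclass
class ResponseForest:
    """All trees grown for one response variable."""

    response: str
    feature_names: list[str]
    classes: np.ndarray
    trees: list[DecisionTree]
    oob_error: float
    n_oob_voters: int


@dataclass
class ImputationModel:
    """The fitted forest plus everything needed to impute and audit it."""

    forests: dict[str, ResponseForest]
    reference: pd.DataFrame
    config: ImputationConfig
    zone: object = None
    warnings: list = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return sum(len(f.trees) for f in self.forests.values())

    @property
    def plot_ids(self) -> np.ndarray:
        return self.reference["plot_id"].to_numpy()


def fit(reference: pd.DataFrame, config: ImputationConfig | None = None) -> ImputationModel:
    """Fit the per-response tree ensembles on the reference plots."""
    config = config or ImputationConfig()
    n = len(reference)
    if n == 0:
        raise ValueError("empty reference table")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 0]))
    n_inbag = max(1, math.floor(config.bootstrap_fraction * n))
    warnings = []

    all_vars = sorted(set(config.predictors) | set(config.responses),
                      key=lambda v: (list(config.predictors) + list(config.responses)).index(v))
    Xall = reference[all_vars].to_numpy(dtype=float)
    col_of = {v: i for i, v in enumerate(all_vars)}

    forests = {}
    for response in config.responses:
        feats = config.feature_names(response)
        cols = [col_of[v] for v in feats]
        var_is_cat = np.array([v in CATEGORICAL_VARS for v in feats])
        X = Xall[:, cols]
        classes, y = np.unique(reference[response].to_numpy(), return_inverse=True)
        mtry = max(1, math.floor(math.sqrt(len(feats))))

        trees = []
        votes = np.zeros((n, classes.size), dtype=np.int64)
        for _ in range(config.trees_per_response):
            inbag = np.sort(rng.choice(n, size=n_inbag, replace=False))
            tree = _grow_tree(X[inbag], y[inbag], classes.size, var_is_cat,
                              config.min_bucket, mtry, rng, inbag)
            flags = np.zeros(n, dtype=bool)
            flags[inbag] = True
            tree.inbag = flags
            oob = np.flatnonzero(~flags)
            if oob.size:
                leaves = tree.apply(X[oob])
                for j, leaf in zip(oob, leaves):
                    votes[j, tree.leaf_majority[int(leaf)]] += 1
            trees.append(tree)

        voted = votes.sum(axis=1) > 0
        if voted.any():
            pred = np.argmax(votes[voted], axis=1)
            oob_error = float(np.mean(pred != y[voted]))
        else:
            oob_error = 0.0
            warnings.append(f"{response}: no out-of-bag observations; OOB error reported as 0")
            log.warning("OOB error undefined for %s (no out-of-bag plots); reporting 0", response)
        forests[response] = ResponseForest(response, feats, classes, trees,
                                           oob_error, int(voted.sum()))
    return ImputationModel(forests, reference.reset_index(drop=True), config,
                           warnings=warnings)


def oob_report(model: ImputationModel) -> pd.DataFrame:
    """Per-response out-of-bag misclassification table."""
    rows = [
        {"response": r, "oob_error": f.oob_error, "n_oob_voters": f.n_oob_voters,
         "n_trees": len(f.trees), "n_classes": f.classes.size}
        for r, f in model.forests.items()
    ]
    return pd.DataFrame(rows)


@dataclass
class ImputedMap:
    """Raster of imputed plot identifiers plus diagnostics and provenance."""

    plot_id: np.ndarray
    vote_margin: np.ndarray
    mask: np.ndarray
    geometry: GridGeometry
    crs: str
    provenance: dict = field(default_factory=dict)
    attributes: pd.DataFrame | None = None

    def attribute_raster(self, name: str, nodata=NODATA_ID) -> np.ndarray:
        """Map the plot-id raster through a reference-table attribute."""
        lut = dict(zip(self.attributes["plot_id"], self.attributes[name]))
        out = np.full(self.plot_id.shape, nodata, dtype=float)
        ids = self.plot_id[self.mask]
        out[self.mask] = np.array([lut[i] for i in ids], dtype=float)
        return out

    def to_dir(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        band = RasterBand(self.plot_id.astype(np.int64), NODATA_ID, self.geometry, self.crs)
        write_ascii_grid(band, out_dir / "plot_id.asc")
        write_ascii_grid(RasterBand(self.vote_margin.astype(np.int64), NODATA_ID,
                                    self.geometry, self.crs), out_dir / "vote_margin.asc")
        if self.attributes is not None:
            self.attributes.to_csv(out_dir / "attributes.csv", index=False)
        import json
        (out_dir / "provenance.json").write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def from_dir(cls, in_dir) -> "ImputedMap":
        in_dir = Path(in_dir)
        band = read_ascii_grid(in_dir / "plot_id.asc", dtype=np.int64)
        margin = read_ascii_grid(in_dir / "vote_margin.asc", dtype=np.int64)
        attrs = None
        if (in_dir / "attributes.csv").exists():
            attrs = pd.read_csv(in_dir / "attributes.csv")
        import json
        prov_path = in_dir / "provenance.json"
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(band.values, margin.values, band.values != NODATA_ID,
                   band.geometry, band.crs, prov, attrs)


def cooccurrence_tally(model: ImputationModel, stack: TargetStack,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """(n_pixels, n_plots) co-occurrence counts over all trees.

    Entry [p, q] is the number of trees (across all response ensembles)
    in whose terminal node pixel ``p`` lands together with in-bag
    reference plot ``q``.  Pixels are the masked pixels in row-major
    order.
    """
    use_mask = stack.mask if mask is None else (stack.mask & mask)
    rows, cols = np.nonzero(use_mask)
    n_pix = rows.size
    n_plots = len(model.reference)
    tally = np.zeros((n_pix, n_plots), dtype=np.int32)
    for forest in model.forests.values():
        Xq = np.column_stack([np.asarray(stack.bands[v], dtype=float)[rows, cols]
                              for v in forest.feature_names])
        for tree in forest.trees:
            leaves = tree.apply(Xq)
            order = np.argsort(leaves, kind="stable")
            sorted_leaves = leaves[order]
            bounds = np.flatnonzero(np.diff(sorted_leaves)) + 1
            for chunk in np.split(order, bounds):
                members = tree.leaf_members.get(int(leaves[chunk[0]]))
                if members is not None and members.size:
                    tally[np.ix_(chunk, members)] += 1
    return tally


def vote_winners(tally: np.ndarray, tie_rng) -> tuple[np.ndarray, np.ndarray]:
    """Modal plot per tally row with uniform random tie-splitting.

    Rows are processed in order, so a given generator state yields a
    reproducible assignment.  Returns (winner index, vote margin); the
    margin is best minus runner-up, 0 whenever the best was tied.
    """
    best = tally.max(axis=1)
    is_best = tally == best[:, None]
    n_best = is_best.sum(axis=1)
    winner = np.argmax(is_best, axis=1)
    for p in np.flatnonzero(n_best > 1):
        choices = np.flatnonzero(is_best[p])
        winner[p] = choices[tie_rng.integers(choices.size)]
    tmp = tally.copy()
    tmp[np.arange(tmp.shape[0]), winner] = -1
    second = tmp.max(axis=1)
    margin = np.where(n_best > 1, 0, best - np.maximum(second, 0))
    return winner, margin


def _check_unseen_evg(model: ImputationModel, stack: TargetStack, mask) -> None:
    present = np.unique(np.asarray(stack.bands["evg"])[mask])
    known = set(int(v) for v in np.unique(model.reference["evg"]))
    missing = sorted(set(int(v) for v in present) - known)
    if missing:
        raise UnresolvedClassError(
            f"target pixels carry EVG codes with no reference plot: {missing}")


def impute(model: ImputationModel, stack: TargetStack,
           mask: np.ndarray | None = None) -> ImputedMap:
    """Assign the modal co-occurring reference plot to every masked pixel.

    Ties for the maximal tally are split uniformly at random by a
    generator seeded from the run seed; pixels are processed in
    row-major order, so results are bit-reproducible.
    """
    use_mask = stack.mask if mask is None else (stack.mask & mask)
    _check_unseen_evg(model, stack, use_mask)
    tally = cooccurrence_tally(model, stack, mask)
    rows, cols = np.nonzero(use_mask)
    tie_rng = np.random.default_rng(np.random.SeedSequence([int(model.config.rng_seed), 1]))
    winner, margin = vote_winners(tally, tie_rng)

    ids = model.plot_ids
    if not np.issubdtype(np.asarray(ids).dtype, np.integer):
        raise ValueError("plot_id must be integer-valued to rasterise")
    plot_raster = np.full(stack.shape, NODATA_ID, dtype=np.int64)
    plot_raster[rows, cols] = ids[winner]
    margin_raster = np.full(stack.shape, NODATA_ID, dtype=np.int64)
    margin_raster[rows, cols] = margin

    provenance = {
        "rng_seed": model.config.rng_seed,
        "trees_per_response": model.config.trees_per_response,
        "responses": list(model.config.responses),
        "n_reference_plots": len(model.reference),
        "oob_errors": {r: f.oob_error for r, f in model.forests.items()},
    }
    return ImputedMap(plot_raster, margin_raster, use_mask, stack.geometry,
                      stack.crs, provenance, model.reference.copy())


def run_zonal(reference: pd.DataFrame, stack: TargetStack,
              zone_band: RasterBand | np.ndarray,
              config: ImputationConfig | None = None) -> tuple[ImputedMap, pd.DataFrame]:
    """Fit and impute independently per map zone and stitch the results.

    Each zone uses only the reference plots whose vegetation group
    occurs among that zone's masked pixels; a zone whose masked pixels
    span more than ``max_classes_per_run`` groups is refused (subdivide
    the zone raster), and a zone with no eligible reference plot raises
    :class:`ZoneSkippedError`.  Returns the stitched map and a per-zone
    out-of-bag report.
    """
    config = config or ImputationConfig()
    if isinstance(zone_band, RasterBand):
        check_aligned(zone_band, RasterBand(np.zeros(stack.shape), 0, stack.geometry, stack.crs))
        zones = np.asarray(zone_band.values).astype(int)
    else:
        zones = np.asarray(zone_band).astype(int)
        if zones.shape != stack.shape:
            from .raster import RasterAlignmentError
            raise RasterAlignmentError("zone raster shape mismatch")

    plot_raster = np.full(stack.shape, NODATA_ID, dtype=np.int64)
    margin_raster = np.full(stack.shape, NODATA_ID, dtype=np.int64)
    reports = []
    zone_codes = np.unique(zones[stack.mask])
    evg = np.asarray(stack.bands["evg"])
    for zi, z in enumerate(zone_codes):
        zmask = (zones == z) & stack.mask
        zone_evgs = set(int(v) for v in np.unique(evg[zmask]))
        if len(zone_evgs) > config.max_classes_per_run:
            raise TooManyClassesError(
                f"zone {z} spans {len(zone_evgs)} vegetation-group classes, above the "
                f"{config.max_classes_per_run}-class budget; subdivide the zone raster")
        zref = reference[reference["evg"].isin(zone_evgs)].reset_index(drop=True)
        if zref.empty:
            raise ZoneSkippedError(f"zone {z} has no reference plot; cannot impute it")
        zconfig = ImputationConfig(**{**config.__dict__,
                                      "rng_seed": int(config.rng_seed) + 10_007 * zi})
        model = fit(zref, zconfig)
        model.zone = int(z)
        zmap = impute(model, stack, mask=zmask)
        plot_raster[zmask] = zmap.plot_id[zmask]
        margin_raster[zmask] = zmap.vote_margin[zmask]
        rep = oob_report(model)
        rep.insert(0, "zone", int(z))
        rep["n_plots"] = len(zref)
        reports.append(rep)

    provenance = {"rng_seed": config.rng_seed, "zones": [int(z) for z in zone_codes],
                  "trees_per_response": config.trees_per_response}
    stitched = ImputedMap(plot_raster, margin_raster, stack.mask, stack.geometry,
                          stack.crs, provenance, reference.copy())
    return stitched, pd.concat(reports, ignore_index=True)
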