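import math

import numpy as np
import pandas as pd
import pytest

from treemap.impute import (
    ImputationConfig,
    ImputedMap,
    TooManyClassesError,
    ZoneSkippedError,
    cooccurrence_tally,
    fit,
    impute,
    oob_report,
    run_zonal,
    vote_winners,
)
from treemap.raster import GridGeometry
from treemap.target_prep import PREDICTOR_BANDS, RESPONSE_BANDS, TargetStack, UnresolvedClassError

ALL_BANDS = list(RESPONSE_BANDS) + list(PREDICTOR_BANDS)


def make_stack_from_rows(rows: pd.DataFrame) -> TargetStack:
    """A one-column raster whose pixels are the given band-value rows."""
    n = len(rows)
    geo = GridGeometry(0.0, 0.0, 30.0, n, 1)
    bands = {b: rows[b].to_numpy(dtype=float).reshape(n, 1) for b in ALL_BANDS}
    return TargetStack(bands, np.ones((n, 1), dtype=bool), geo, "AEQD:45:-114")


def random_reference(rng, n_plots, n_evg=3):
    """Well-spread random plots with arbitrary but consistent responses."""
    ref = pd.DataFrame({
        "plot_id": np.arange(1, n_plots + 1),
        "lat": rng.uniform(44, 46, n_plots),
        "lon": rng.uniform(-115, -113, n_plots),
        "slope": rng.uniform(0, 40, n_plots),
        "aspect": rng.uniform(0, 360, n_plots),
        "elevation": rng.uniform(500, 2500, n_plots),
        "par": rng.uniform(300, 600, n_plots),
        "precip": rng.uniform(300, 1500, n_plots),
        "rh": rng.uniform(20, 80, n_plots),
        "tmax": rng.uniform(5, 30, n_plots),
        "tmin": rng.uniform(-10, 10, n_plots),
        "vpd": rng.uniform(5, 25, n_plots),
        "dist_code": rng.integers(0, 2, n_plots),
        "evg": rng.integers(0, n_evg, n_plots) + 613,
        "cover_bin": rng.choice([15, 35, 55, 75, 95], n_plots),
        "height_bin": rng.choice([3, 8, 18, 38, 70], n_plots),
    })
    ref["dist_year"] = np.where(ref.dist_code > 0, 2005, 0)
    return ref


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"trees_per_response": 0},
        {"bootstrap_fraction": 1.0},
        {"min_bucket": 1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ImputationConfig(**kwargs)

    def test_default_tree_count_is_249(self, small_model):
        assert small_model.n_trees == 249

    def test_mtry_is_sqrt_of_candidates(self):
        cfg = ImputationConfig()
        k = len(cfg.feature_names("cover_bin"))
        assert math.floor(math.sqrt(k)) >= 3


class TestFit:
    def test_single_plot_degenerates_to_one_leaf_with_warning(self, rng):
        ref = random_reference(rng, 1)
        model = fit(ref, ImputationConfig(rng_seed=0, trees_per_response=5))
        assert model.warnings  # OOB undefined, reported as 0
        rep = oob_report(model)
        assert (rep["oob_error"] == 0.0).all()
        stack = make_stack_from_rows(ref)
        imap = impute(model, stack)
        assert (imap.plot_id[stack.mask] == ref.plot_id.iloc[0]).all()

    def test_separable_clusters_have_zero_oob(self, rng):
        # two clusters far apart in every predictor, responses pure per
        # cluster: any candidate draw separates them cleanly
        n = 40
        ref = random_reference(rng, n)
        half = n // 2
        cluster = np.repeat([0.0, 1.0], half)
        for col in ("lat", "lon", "slope", "aspect", "elevation", "par", "precip",
                    "rh", "tmax", "tmin", "vpd"):
            ref[col] = ref[col] + cluster * 100 * max(1.0, ref[col].abs().max())
        ref["dist_code"] = cluster.astype(int)
        ref["dist_year"] = np.where(cluster > 0, 2005, 0)
        for col, vals in (("cover_bin", (15, 75)), ("height_bin", (3, 38)), ("evg", (613, 615))):
            ref.loc[:half - 1, col] = vals[0]
            ref.loc[half:, col] = vals[1]
        model = fit(ref, ImputationConfig(rng_seed=1, responses_as_split_candidates=False))
        rep = oob_report(model)
        assert (rep["oob_error"] == 0.0).all()

    def test_shuffled_labels_hit_permutation_null(self, rng):
        # with labels carrying no signal the OOB error approaches (k-1)/k
        n, k = 240, 4
        ref = random_reference(rng, n)
        ref["cover_bin"] = np.tile([15, 35, 55, 75], n // k)
        ref["cover_bin"] = rng.permutation(ref["cover_bin"].to_numpy())
        cfg = ImputationConfig(rng_seed=2, responses=("cover_bin",),
                               responses_as_split_candidates=False)
        model = fit(ref, cfg)
        err = model.forests["cover_bin"].oob_error
        assert abs(err - (k - 1) / k) < 0.08

    def test_leaf_members_sum_to_bootstrap_size(self, small_model, small_tables):
        n = len(small_tables.reference)
        expected = math.floor(0.66 * n)
        for forest in small_model.forests.values():
            for tree in forest.trees:
                assert sum(len(m) for m in tree.leaf_members.values()) == expected
                assert tree.inbag.sum() == expected

    def test_matches_sklearn_forest_on_same_data(self, small_tables):
        sklearn = pytest.importorskip("sklearn.ensemble")
        ref = small_tables.reference
        cfg = ImputationConfig(rng_seed=3, responses=("cover_bin",),
                               responses_as_split_candidates=False)
        model = fit(ref, cfg)
        X = ref[cfg.feature_names("cover_bin")].to_numpy(float)
        y = ref["cover_bin"].to_numpy()
        rf = sklearn.RandomForestClassifier(83, min_samples_leaf=5, oob_score=True,
                                            random_state=0)
        rf.fit(X, y)
        mine = 1.0 - model.forests["cover_bin"].oob_error
        assert abs(mine - rf.oob_score_) < 0.12


class TestImpute:
    def test_deterministic_under_fixed_seed(self, small_tables, small_synth):
        cfg = ImputationConfig(rng_seed=11)
        a = impute(fit(small_tables.reference, cfg), small_synth.stack)
        b = impute(fit(small_tables.reference, cfg), small_synth.stack)
        np.testing.assert_array_equal(a.plot_id, b.plot_id)
        np.testing.assert_array_equal(a.vote_margin, b.vote_margin)

    def test_exact_match_pixel_gets_its_plot(self, rng):
        # a pixel identical to a well-separated plot is assigned that plot
        ref = random_reference(rng, 10)
        ref["elevation"] = np.arange(10) * 500.0  # spread plots far apart
        # min_bucket 2: with ten plots the default bucket of five could
        # never split the six-plot bootstrap at all
        model = fit(ref, ImputationConfig(rng_seed=4, trees_per_response=30, min_bucket=2))
        stack = make_stack_from_rows(ref)
        imap = impute(model, stack)
        match = imap.plot_id[stack.mask] == ref.plot_id.to_numpy()
        assert match.mean() >= 0.9

    def test_recovery_from_noisy_plot_vectors(self, rng):
        # pixels are plot vectors plus small noise: imputed attributes
        # recover the generating plot's responses on >= 90% of pixels
        ref = random_reference(rng, 50)
        reps = 8
        gen = np.repeat(np.arange(50), reps)
        rows = ref.iloc[gen].reset_index(drop=True).copy()
        for col in ("lat", "lon", "slope", "aspect", "elevation", "par", "precip",
                    "rh", "tmax", "tmin", "vpd"):
            scale = rows[col].std() * 0.01
            rows[col] = rows[col] + rng.normal(0, scale, len(rows))
        stack = make_stack_from_rows(rows)
        model = fit(ref, ImputationConfig(rng_seed=5))
        imap = impute(model, stack)
        ids = imap.plot_id[stack.mask]
        lut = ref.set_index("plot_id")
        rate = np.mean([
            (lut.loc[i, "cover_bin"] == lut.loc[g + 1, "cover_bin"])
            and (lut.loc[i, "height_bin"] == lut.loc[g + 1, "height_bin"])
            and (lut.loc[i, "evg"] == lut.loc[g + 1, "evg"])
            for i, g in zip(ids, gen)])
        assert rate >= 0.9

    def test_unseen_evg_class_is_an_error(self, rng):
        ref = random_reference(rng, 20)
        model = fit(ref, ImputationConfig(rng_seed=6, trees_per_response=5))
        rows = ref.head(4).copy()
        rows.loc[rows.index[0], "evg"] = 999
        stack = make_stack_from_rows(rows)
        with pytest.raises(UnresolvedClassError, match="999"):
            impute(model, stack)

    def test_unseen_noncritical_level_routes_to_bigger_child(self, rng):
        ref = random_reference(rng, 30)
        model = fit(ref, ImputationConfig(rng_seed=7, trees_per_response=10))
        rows = ref.head(5).copy()
        rows["dist_code"] = 7  # level never seen in training
        stack = make_stack_from_rows(rows)
        imap = impute(model, stack)  # must not raise
        assert set(imap.plot_id[stack.mask]) <= set(ref.plot_id)

    def test_tie_splitting_is_uniform(self):
        # 1000 rows, two tied columns: winners split 50/50 within the
        # binomial 99% interval
        tally = np.tile(np.array([[7, 7, 3]], dtype=np.int32), (1000, 1))
        winner, margin = vote_winners(tally, np.random.default_rng(123))
        n0 = int((winner == 0).sum())
        assert 459 <= n0 <= 541
        assert (margin == 0).all()

    def test_margin_positive_without_tie(self):
        tally = np.array([[5, 2, 1], [9, 9, 1]], dtype=np.int32)
        winner, margin = vote_winners(tally, np.random.default_rng(0))
        assert winner[0] == 0 and margin[0] == 3
        assert margin[1] == 0


class TestOracleEquivalence:
    @staticmethod
    def naive_route(tree, x):
        nid = 0
        while tree.feature[nid] >= 0:
            f = tree.feature[nid]
            if tree.left_cats[nid] is not None:
                v = x[f]
                if v in set(tree.left_cats[nid].tolist()):
                    nid = tree.left[nid]
                elif v in set(tree.right_cats[nid].tolist()):
                    nid = tree.right[nid]
                elif tree.n_node[tree.left[nid]] >= tree.n_node[tree.right[nid]]:
                    nid = tree.left[nid]
                else:
                    nid = tree.right[nid]
            elif x[f] <= tree.threshold[nid]:
                nid = tree.left[nid]
            else:
                nid = tree.right[nid]
        return nid

    def test_tally_equals_naive_leaf_intersection(self, rng):
        """Engine co-occurrence counts equal an explicit per-pixel,
        per-plot leaf-membership intersection recomputed from scratch."""
        ref = random_reference(rng, 40)
        cfg = ImputationConfig(rng_seed=8, trees_per_response=5)
        model = fit(ref, cfg)
        rows = ref.sample(25, random_state=1, replace=True).reset_index(drop=True)
        stack = make_stack_from_rows(rows)
        engine = cooccurrence_tally(model, stack)

        naive = np.zeros_like(engine)
        prow, pcol = np.nonzero(stack.mask)
        for forest in model.forests.values():
            Xref = ref[forest.feature_names].to_numpy(float)
            Xpix = np.column_stack([stack.bands[v][prow, pcol] for v in forest.feature_names])
            for tree in forest.trees:
                plot_leaf = {q: self.naive_route(tree, Xref[q])
                             for q in np.flatnonzero(tree.inbag)}
                for p in range(Xpix.shape[0]):
                    leaf = self.naive_route(tree, Xpix[p])
                    for q, ql in plot_leaf.items():
                        if ql == leaf:
                            naive[p, q] += 1
        np.testing.assert_array_equal(engine, naive)


class TestZonal:
    def test_single_zone_equals_direct_fit(self, small_tables, small_synth):
        stack = small_synth.stack
        cfg = ImputationConfig(rng_seed=11)
        direct = impute(fit(small_tables.reference, cfg), stack)
        zones = np.zeros(stack.shape, dtype=int)
        zonal, report = run_zonal(small_tables.reference, stack, zones, cfg)
        np.testing.assert_array_equal(direct.plot_id, zonal.plot_id)
        assert set(report["zone"]) == {0}

    def test_disjoint_evg_zones_never_cross(self, small_tables, small_synth):
        stack = small_synth.stack
        evg = stack.band("evg")
        codes = sorted(np.unique(evg[stack.mask]))
        set_a = set(codes[: len(codes) // 2])
        zones = np.where(np.isin(evg, list(set_a)), 1, 2)
        zonal, _ = run_zonal(small_tables.reference, stack, zones,
                             ImputationConfig(rng_seed=11))
        lut = small_tables.reference.set_index("plot_id")["evg"].to_dict()
        in_b = stack.mask & (zones == 2)
        imputed_evgs_b = {lut[i] for i in zonal.plot_id[in_b]}
        assert imputed_evgs_b.isdisjoint(set_a)

    def test_class_budget_refusal(self, small_tables, small_synth):
        stack = small_synth.stack
        zones = np.zeros(stack.shape, dtype=int)
        with pytest.raises(TooManyClassesError):
            run_zonal(small_tables.reference, stack, zones,
                      ImputationConfig(rng_seed=0, max_classes_per_run=2))

    def test_zone_without_plots_is_an_error(self, small_tables, small_synth, rng):
        stack = small_synth.stack
        reference = small_tables.reference[small_tables.reference["evg"] == -1]
        zones = np.zeros(stack.shape, dtype=int)
        with pytest.raises((ZoneSkippedError, ValueError)):
            run_zonal(reference, stack, zones, ImputationConfig(rng_seed=0))


def test_imputed_map_round_trip(tmp_path, small_imputed):
    small_imputed.to_dir(tmp_path / "imp")
    back = ImputedMap.from_dir(tmp_path / "imp")
    np.testing.assert_array_equal(back.plot_id, small_imputed.plot_id)
    np.testing.assert_array_equal(back.mask, small_imputed.mask)
    assert back.attributes is not None
    cov = back.attribute_raster("cover_bin")
    assert cov.shape == small_imputed.plot_id.shape
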