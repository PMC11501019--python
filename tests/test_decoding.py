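"""Searchlight features, LOO SVM, permutation test, clusters, ROIs."""

import numpy as np
import pytest

from obpc.decoding import (
    CLASS_ORDER,
    AccuracyMap,
    FeatureTable,
    RoiWindow,
    accuracy_power_regression,
    build_features,
    cluster_mask,
    find_clusters,
    loo_decode,
    overlap_report,
    permutation_test,
    roi_summary,
)
from obpc.spectral import CoherenceMap, TFGrid


def make_maps(stack, grid):
    """stack: (P, 2, nf, nt) -> participant->class->CoherenceMap dict."""
    out = {}
    for pi in range(stack.shape[0]):
        out[f"P{pi:02d}"] = {
            c: CoherenceMap(
                C=stack[pi, ci].copy(), grid=grid, pair=("OB", "PC"),
                m=np.full(grid.shape, 40), participant_id=f"P{pi:02d}",
                condition=c,
            )
            for ci, c in enumerate(CLASS_ORDER)
        }
    return out


@pytest.fixture(scope="module")
def grid12():
    return TFGrid(freqs=np.arange(4.0, 16.0), times=np.arange(0.0, 0.6, 0.05))


class TestBuildFeatures:
    def test_interior_center_has_121_features(self, rng, grid12):
        stack = rng.random((4, 2, 12, 12))
        ft = build_features(make_maps(stack, grid12), grid12)
        k = np.flatnonzero((ft.center_idx == [5, 5]).all(axis=1))[0]
        assert ft.features[k].shape == (8, 121)

    def test_corner_center_truncated_but_valid(self, rng, grid12):
        stack = rng.random((4, 2, 12, 12))
        ft = build_features(make_maps(stack, grid12), grid12)
        k = np.flatnonzero((ft.center_idx == [0, 0]).all(axis=1))[0]
        assert ft.features[k].shape == (8, 36)  # 6 x 6 corner neighborhood

    def test_centers_with_few_valid_neighbors_excluded(self, rng, grid12):
        stack = rng.random((4, 2, 12, 12))
        stack[:, :, :, 2:] = np.nan  # only two valid columns
        ft = build_features(make_maps(stack, grid12), grid12)
        # corner (0,0): neighborhood 6x2 = 12 valid >= 10 -> kept;
        # every center keeps >= 10 of the two remaining columns except none
        assert ft.valid_centers[:, :2].any()
        assert not ft.valid_centers[:, 2:].any()
        counts = [f.shape[1] for f in ft.features]
        assert min(counts) >= 10

    def test_constant_map_gives_identical_vectors(self, grid12):
        stack = np.ones((3, 2, 12, 12))
        ft = build_features(make_maps(stack, grid12), grid12)
        X = ft.features[0]
        assert np.ptp(X) == 0


class TestLooDecode:
    def test_separable_offset_gives_perfect_accuracy(self, rng, grid12):
        stack = rng.random((6, 2, 12, 12)) * 0.05
        stack[:, 0] += 0.5  # unpleasant maps uniformly offset
        acc = loo_decode(build_features(make_maps(stack, grid12), grid12))
        assert np.nanmin(acc.A) == 1.0

    def test_fold_accuracies_quantized(self, rng, grid12):
        stack = rng.random((5, 2, 12, 12))
        acc = loo_decode(build_features(make_maps(stack, grid12), grid12))
        vals = acc.per_participant[np.isfinite(acc.per_participant)]
        assert set(np.unique(vals)).issubset({0.0, 0.5, 1.0})

    def test_null_features_decode_at_chance(self, rng):
        grid = TFGrid(freqs=np.arange(4.0, 20.0), times=np.arange(0.0, 0.8, 0.05))
        accs = []
        for _ in range(5):
            stack = rng.random((12, 2, 16, 16))
            acc = loo_decode(build_features(make_maps(stack, grid), grid))
            accs.append(np.nanmean(acc.A))
        assert abs(np.mean(accs) - 0.5) < 0.04

    def test_needs_three_participants(self, rng, grid12):
        stack = rng.random((2, 2, 12, 12))
        with pytest.raises(ValueError, match="participants"):
            loo_decode(build_features(make_maps(stack, grid12), grid12))

    def test_matches_sklearn_svc_predictions(self, rng):
        """Fold-wise parity with SVC(kernel='linear', C=1) on standardized
        features; ties/boundary cases make exact parity impossible, so
        >= 95% prediction agreement is required."""
        sklearn = pytest.importorskip("sklearn.svm")
        from obpc._svm import fold_grams
        from obpc.decoding import _loo_with_predictions

        agree = tot = 0
        for rep in range(20):
            P, d = 8, 15
            X = rng.standard_normal((2 * P, d))
            if rep % 2:
                X[::2] += 0.4
            G = fold_grams(X)
            _, pred = _loo_with_predictions(G, 1.0, 1e-4, 2000)
            y = np.tile([0, 1], P)
            for i in range(P):
                mask = np.ones(2 * P, bool)
                mask[2 * i: 2 * i + 2] = False
                mu = X[mask].mean(0)
                sd = X[mask].std(0)
                sd[sd == 0] = 1
                Z = (X - mu) / sd
                clf = sklearn.SVC(kernel="linear", C=1.0).fit(Z[mask], y[mask])
                skp = clf.predict(Z[2 * i: 2 * i + 2])
                agree += (skp == pred[i]).sum()
                tot += 2
        assert agree / tot >= 0.95


class TestPermutationTest:
    def test_perfect_decoding_hits_formula_floor(self, rng, grid12):
        stack = rng.random((6, 2, 12, 12)) * 0.05
        stack[:, 0] += 0.5
        ft = build_features(make_maps(stack, grid12), grid12)
        acc = loo_decode(ft)
        n_perm = 99
        res = permutation_test(ft, acc, n_perm=n_perm,
                               rng=np.random.default_rng(0))
        # offset survives any class swap, so only the identity-like
        # permutations tie the observed accuracy
        assert np.nanmin(res.p) >= 1 / (n_perm + 1)
        assert (res.p[np.isfinite(res.p)] <= 1).all()

    def test_identical_class_maps_give_p_near_one(self, rng, grid12):
        stack = rng.random((6, 1, 12, 12))
        stack = np.concatenate([stack, stack], axis=1)
        ft = build_features(make_maps(stack, grid12), grid12)
        acc = loo_decode(ft)
        res = permutation_test(ft, acc, n_perm=199,
                               rng=np.random.default_rng(0))
        assert np.nanmedian(res.p) > 0.9

    def test_sequential_matches_full_significance_decision(self, rng):
        grid = TFGrid(freqs=np.arange(4.0, 12.0), times=np.arange(0.0, 0.4, 0.05))
        stack = rng.random((8, 2, 8, 8))
        stack[:, 0, 2:5, 2:5] += 0.4  # localized effect
        ft = build_features(make_maps(stack, grid), grid)
        acc = loo_decode(ft)
        full = permutation_test(ft, acc, n_perm=200,
                                rng=np.random.default_rng(5))
        seq = permutation_test(ft, acc, n_perm=200,
                               rng=np.random.default_rng(5),
                               sequential_alpha=0.01)
        np.testing.assert_array_equal(
            np.nan_to_num(full.p) < 0.01, np.nan_to_num(seq.p) < 0.01
        )

    def test_low_n_perm_warns(self, rng, grid12):
        stack = rng.random((4, 2, 12, 12))
        ft = build_features(make_maps(stack, grid12), grid12)
        acc = loo_decode(ft)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(ft, acc, n_perm=50, rng=np.random.default_rng(0))


class TestClusters:
    def _grid(self, nf, nt):
        return TFGrid(freqs=np.arange(4.0, 4.0 + nf),
                      times=np.arange(0.0, nt * 0.05, 0.05))

    def test_no_significant_points_no_clusters(self):
        p = np.full((6, 6), 0.5)
        assert find_clusters(p, self._grid(6, 6)) == []

    def test_single_point_cluster(self):
        p = np.full((6, 6), 0.5)
        p[2, 3] = 0.001
        cl = find_clusters(p, self._grid(6, 6))
        assert len(cl) == 1
        assert cl[0].members.tolist() == [[2, 3]]

    def test_diagonal_blobs_are_separate_under_4_connectivity(self):
        p = np.full((8, 8), 0.5)
        p[1:3, 1:3] = 0.001
        p[3, 3] = 0.001  # touches only diagonally
        clusters = find_clusters(p, self._grid(8, 8))
        assert len(clusters) == 2
        mask = cluster_mask(clusters, (8, 8))
        assert mask.sum() == 5

    def test_blobs_split_by_nonsignificant_column(self):
        p = np.full((6, 9), 0.5)
        p[2:4, 1:3] = 0.005
        p[2:4, 5:7] = 0.005
        clusters = find_clusters(p, self._grid(6, 9))
        assert len(clusters) == 2


class TestRoiSummary:
    def _acc_map(self, per, preds, grid):
        import warnings

        P = per.shape[0]
        valid = np.isfinite(per).all(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            A = np.nanmean(per, axis=0)
        return AccuracyMap(
            A=A, per_participant=per,
            predictions=preds, grid=grid,
            participants=[f"P{i}" for i in range(P)], valid=valid,
        )

    def test_perfect_decoding_identity_confusion(self):
        grid = TFGrid(freqs=np.arange(4.0, 10.0), times=np.arange(0.0, 0.3, 0.05))
        P = 4
        per = np.ones((P, 6, 6))
        preds = np.zeros((6, 6, P, 2), dtype=np.int8)
        preds[:, :, :, 1] = 1  # each true class predicted as itself
        roi = RoiWindow("all", (4.0, 9.0), (0.0, 0.25))
        res = roi_summary(self._acc_map(per, preds, grid), roi)
        np.testing.assert_allclose(res["confusion"], np.eye(2))
        assert res["mean_accuracy"] == 1.0

    def test_chance_rows_near_half(self, rng):
        grid = TFGrid(freqs=np.arange(4.0, 10.0), times=np.arange(0.0, 0.3, 0.05))
        P = 10
        preds = rng.integers(0, 2, size=(6, 6, P, 2)).astype(np.int8)
        per = (preds == np.array([0, 1])).mean(axis=3).transpose(2, 0, 1)
        roi = RoiWindow("all", (4.0, 9.0), (0.0, 0.25))
        res = roi_summary(self._acc_map(per, preds, grid), roi)
        assert res["confusion"].sum(axis=1) == pytest.approx([1.0, 1.0])
        assert np.abs(res["confusion"] - 0.5).max() < 0.1

    def test_empty_roi_rejected(self, rng):
        grid = TFGrid(freqs=np.arange(4.0, 10.0), times=np.arange(0.0, 0.3, 0.05))
        per = np.full((3, 6, 6), np.nan)
        preds = np.full((6, 6, 3, 2), -1, dtype=np.int8)
        roi = RoiWindow("all", (4.0, 9.0), (0.0, 0.25))
        with pytest.raises(ValueError, match="no valid"):
            roi_summary(self._acc_map(per, preds, grid), roi)


class TestOverlapAndRegression:
    def test_jaccard_of_identical_masks_is_one(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        rep = overlap_report(m, m)
        assert rep["jaccard"] == 1.0 and rep["n_overlap"] == 4

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        rep = overlap_report(a, b)
        assert rep["jaccard"] == 0.0 and rep["n_overlap"] == 0

    def test_affine_relation_recovered(self, rng):
        power = rng.standard_normal(25)
        acc = 0.5 + 0.07 * power
        res = accuracy_power_regression(acc, {"OB": power})
        assert res["OB"]["slope"] == pytest.approx(0.07, rel=1e-6)
        assert res["OB"]["p"] < 1e-10

    def test_independent_power_not_significant(self, rng):
        ps = [
            accuracy_power_regression(
                rng.random(20), {"OB": rng.standard_normal(20)}
            )["OB"]["p"]
            for _ in range(20)
        ]
        assert np.mean(np.array(ps) < 0.05) <= 0.25

    def test_zero_variance_regressor_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            accuracy_power_regression(rng.random(10), {"OB": np.ones(10)})
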