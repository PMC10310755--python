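import itertools

import numpy as np
import pandas as pd
import pytest

from spinemorph import cluster


def blobs(k, n_per, sep=20.0, sd=1.0, seed=0):
    """k Gaussian blobs at mutually equidistant centres (scaled simplex)."""
    rng = np.random.default_rng(seed)
    centers = sep * np.eye(k)
    X = np.vstack([rng.normal(c, sd, size=(n_per, k)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestKMeans:
    def test_k_equals_n_zero_wss(self, rng):
        X = rng.random((8, 3))
        res = cluster.kmeans_cluster(X, k=8, rng=0)
        assert res.parameters["inertia"] == pytest.approx(0.0, abs=1e-12)

    def test_k_one_centroid_is_mean(self, rng):
        X = rng.random((20, 3))
        res = cluster.kmeans_cluster(X, k=1, rng=0)
        wss = ((X - X.mean(axis=0)) ** 2).sum()
        assert res.parameters["inertia"] == pytest.approx(wss, rel=1e-9)

    def test_recovers_separated_blobs(self):
        X, truth = blobs(3, 50, sep=30)
        res = cluster.kmeans_cluster(X, k=3, rng=0)
        # identical partition up to relabeling
        df = pd.crosstab(truth, res.assignments)
        assert (df.to_numpy() > 0).sum() == 3

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster.kmeans_cluster(rng.random((5, 2)), k=6)


class TestDBSCAN:
    def test_huge_eps_single_cluster(self, rng):
        X = rng.random((30, 3))
        res = cluster.dbscan_cluster(X, eps=100.0)
        assert res.k == 1
        assert (res.assignments != cluster.NOISE).all()

    def test_tiny_eps_all_noise(self, rng):
        X = rng.random((30, 3))
        res = cluster.dbscan_cluster(X, eps=1e-9)
        assert (res.assignments == cluster.NOISE).all()

    def test_two_blobs_one_outlier(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0, 0], 0.1, size=(20, 2))
        b = rng.normal([5, 5], 0.1, size=(20, 2))
        X = np.vstack([a, b, [[500.0, 500.0]]])
        res = cluster.dbscan_cluster(X, eps=1.0, min_neighbors=4)
        assert res.k == 2
        assert (res.assignments == cluster.NOISE).sum() == 1

    def test_jsd_requires_normalized_rows(self, rng):
        X = rng.random((10, 5))
        with pytest.raises(ValueError, match="normalized"):
            cluster.dbscan_cluster(X, eps=0.1, metric="jensen_shannon")

    def test_jsd_metric_matches_scalar_jsd(self, rng):
        from spinemorph.cldh import jensen_shannon_distance

        X = rng.random((12, 8))
        X /= X.sum(axis=1, keepdims=True)
        d01 = jensen_shannon_distance(X[0], X[1])
        res = cluster.dbscan_cluster(X, eps=d01 + 1e-9, min_neighbors=1,
                                     metric="jensen_shannon")
        # rows 0 and 1 are neighbours under the shared JSD implementation
        assert res.assignments[0] == res.assignments[1]


class TestCurves:
    def test_wss_matches_brute_force(self, rng):
        X = rng.random((40, 3))
        for k in (2, 3):
            # one-point grids so the curve and the standalone clustering
            # consume the seed stream identically
            curve = cluster.wss_curve(X, [k], rng=7)
            res = cluster.kmeans_cluster(X, k, rng=np.random.default_rng(7))
            wss = 0.0
            for cid in range(1, res.k + 1):
                pts = X[res.assignments == cid]
                wss += ((pts - pts.mean(axis=0)) ** 2).sum()
            assert curve.scores[0] == pytest.approx(wss, rel=1e-9)

    def test_wss_zero_at_k_equals_n(self, rng):
        X = rng.random((6, 2))
        curve = cluster.wss_curve(X, [6], rng=0)
        assert curve.scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_phi_boundaries(self, rng):
        X = rng.random((50, 3))
        curve = cluster.dbscan_phi_curve(X, [1e-12, 100.0])
        assert curve.scores[0] == 50
        assert curve.scores[-1] == 0

    def test_phi_matches_brute_force(self, rng):
        X = rng.random((50, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d3 = np.sort(D, axis=1)[:, 3]
        eps_grid = np.linspace(0.05, 1.0, 7)
        curve = cluster.dbscan_phi_curve(X, eps_grid)
        expected = [(d3 > e).sum() for e in eps_grid]
        np.testing.assert_array_equal(curve.scores, expected)


class TestElbow:
    def test_piecewise_linear_breakpoint(self):
        grid = np.arange(1, 8, dtype=float)
        scores = np.where(grid <= 3, 10 - 3 * grid, 1 - 0.0 * grid)
        curve = cluster.QualityCurve(grid=grid, scores=scores, criterion="wss")
        assert cluster.elbow_point(curve) == 3

    def test_straight_line_warns(self):
        curve = cluster.QualityCurve(
            grid=np.arange(5.0), scores=10 - 2 * np.arange(5.0),
            criterion="wss")
        with pytest.warns(UserWarning, match="no elbow"):
            assert cluster.elbow_point(curve) == 1.0  # smallest interior

    def test_five_blob_wss_elbow(self):
        X, _ = blobs(5, 40, sep=40, seed=3)
        curve = cluster.wss_curve(X, list(range(2, 10)), rng=0)
        assert cluster.elbow_point(curve) == 5

    def test_too_few_points_rejected(self):
        curve = cluster.QualityCurve(grid=np.array([1.0, 2.0]),
                                     scores=np.array([1.0, 0.0]),
                                     criterion="wss")
        with pytest.raises(ValueError):
            cluster.elbow_point(curve)


class TestSilhouette:
    def test_tight_blobs_high_score(self):
        X, _ = blobs(2, 50, sep=100, sd=0.5, seed=4)
        res = cluster.kmeans_cluster(X, 2, rng=0)
        assert cluster.silhouette(X, res) > 0.95

    def test_random_labels_near_zero(self, rng):
        X = rng.normal(size=(500, 4))
        assignments = rng.integers(1, 4, size=500)
        res = cluster.ClusteringResult(assignments=assignments, k=3,
                                       algorithm="kmeans", parameters={})
        assert abs(cluster.silhouette(X, res)) < 0.1

    def test_single_cluster_rejected(self, rng):
        X = rng.random((10, 2))
        res = cluster.kmeans_cluster(X, 1, rng=0)
        with pytest.raises(ValueError):
            cluster.silhouette(X, res)


class TestClassDivergence:
    def result_from(self, assignments):
        a = np.asarray(assignments)
        return cluster.ClusteringResult(assignments=a, k=int(a.max()),
                                        algorithm="kmeans", parameters={})

    def test_identical_composition_zero(self):
        res = self.result_from([1, 1, 2, 2])
        classes = ["mushroom", "thin", "mushroom", "thin"]
        assert cluster.class_divergence_score(res, classes) == pytest.approx(0)

    def test_pure_disjoint_is_one(self):
        res = self.result_from([1, 1, 2, 2])
        classes = ["mushroom", "mushroom", "thin", "thin"]
        assert cluster.class_divergence_score(res, classes) == pytest.approx(1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        assignments = rng.integers(1, 5, size=n)
        classes = rng.choice(["mushroom", "thin", "stubby"], size=n)
        res = self.result_from(assignments)
        # brute force: build M row by row, average pairwise distances
        clusters = sorted(set(assignments))
        class_names = sorted(set(classes))
        M = []
        for c in clusters:
            sel = classes[assignments == c]
            M.append([np.mean(sel == y) for y in class_names])
        M = np.asarray(M)
        dists = [np.linalg.norm(M[i] - M[j])
                 for i, j in itertools.combinations(range(len(M)), 2)]
        expected = np.mean(dists) / np.sqrt(2)
        assert cluster.class_divergence_score(res, classes) == pytest.approx(
            expected, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        assignments = rng.integers(1, 4, size=50)
        classes = rng.choice(["a", "b", "c"], size=50)
        res = self.result_from(assignments)
        s0 = cluster.class_divergence_score(res, classes)
        perm = {1: 3, 2: 1, 3: 2}
        res2 = self.result_from([perm[a] for a in assignments])
        assert cluster.class_divergence_score(res2, classes) == pytest.approx(s0)

    def test_single_cluster_rejected(self):
        res = self.result_from([1, 1, 1])
        with pytest.raises(ValueError):
            cluster.class_divergence_score(res, ["a", "b", "a"])


class TestSelection:
    def test_all_criteria_recover_five_blobs(self):
        X, truth = blobs(5, 40, sep=50, sd=1.0, seed=6)
        names = np.array(["mushroom", "thin", "stubby", "filopodia",
                          "outlier"])
        classes = names[truth]
        for criterion in ("elbow", "silhouette", "divergence"):
            k, curve = cluster.select_cluster_number(
                X, classes=classes, k_grid=range(2, 9), criterion=criterion,
                rng=0)
            assert k == 5, criterion

    @pytest.mark.parametrize("k_true", [3, 4])
    def test_parameter_recovery(self, k_true):
        X, truth = blobs(k_true, 30, sep=40, sd=1.0, seed=7)
        classes = np.array([f"c{t}" for t in truth])
        for criterion in ("elbow", "silhouette", "divergence"):
            k, _ = cluster.select_cluster_number(
                X, classes=classes, k_grid=range(2, 8), criterion=criterion,
                rng=1)
            assert k == k_true, criterion

    def test_divergence_requires_classes(self, rng):
        with pytest.raises(ValueError):
            cluster.select_cluster_number(rng.random((20, 3)), criterion="divergence")

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster.select_cluster_number(rng.random((20, 3)), k_grid=[],
                                          criterion="elbow")


class TestProjection:
    def test_pca_preserves_2d_geometry(self, rng):
        X = rng.normal(size=(30, 2))
        Y = cluster.project_2d(X, "pca")
        dx = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        dy = np.linalg.norm(Y[:, None] - Y[None, :], axis=2)
        np.testing.assert_allclose(dx, dy, atol=1e-9)

    def test_pca_axis_variance_ordered(self, rng):
        X = rng.normal(size=(50, 6)) * np.array([5, 3, 1, 1, 1, 1])
        Y = cluster.project_2d(X, "pca")
        assert Y[:, 0].var() >= Y[:, 1].var()

    def test_tsne_seed_determinism(self, rng):
        X = rng.normal(size=(40, 5))
        a = cluster.project_2d(X, "tsne", rng=3)
        b = cluster.project_2d(X, "tsne", rng=3)
        np.testing.assert_array_equal(a, b)


class TestEnrichment:
    def test_rows_sum_to_one(self, rng):
        assignments = rng.integers(1, 4, size=60)
        classes = rng.choice(["mushroom", "thin", "stubby"], size=60)
        res = cluster.ClusteringResult(assignments=assignments, k=3,
                                       algorithm="kmeans", parameters={})
        cic, cinc = cluster.enrichment_tables(res, classes)
        np.testing.assert_allclose(cic.sum(axis=1), 1.0)
        np.testing.assert_allclose(cinc.sum(axis=1), 1.0)

    def test_pure_clusters_identity_like(self):
        assignments = np.array([1, 1, 2, 2, 3, 3])
        classes = ["mushroom", "mushroom", "thin", "thin", "stubby", "stubby"]
        res = cluster.ClusteringResult(assignments=assignments, k=3,
                                       algorithm="kmeans", parameters={})
        cic, cinc = cluster.enrichment_tables(res, classes)
        assert (cic.to_numpy().max(axis=1) == 1.0).all()
        assert (cinc.to_numpy().max(axis=1) == 1.0).all()

    def test_matches_counting_oracle(self, rng):
        assignments = rng.integers(1, 3, size=40)
        classes = rng.choice(["a", "b"], size=40)
        res = cluster.ClusteringResult(assignments=assignments, k=2,
                                       algorithm="kmeans", parameters={})
        cic, _ = cluster.enrichment_tables(res, classes)
        for c in (1, 2):
            sel = classes[assignments == c]
            for y in ("a", "b"):
                if y in cic.columns:
                    assert cic.loc[c, y] == pytest.approx(np.mean(sel == y))
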