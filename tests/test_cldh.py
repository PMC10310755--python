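import numpy as np
import pytest
import trimesh

from spinemorph import cldh


class TestSurfaceSampling:
    def test_single_triangle_points_inside(self, rng):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]])
        p1, p2 = cldh.sample_surface_pair(tri, rng)
        for p in (p1, p2):
            assert abs(p[2]) < 1e-12
            assert p[0] >= -1e-12 and p[1] >= -1e-12
            assert p[0] + p[1] <= 1 + 1e-12

    def test_sphere_sampling_centered(self, icosphere):
        pts = cldh._sample_surface(icosphere, 100_000, np.random.default_rng(3))
        assert np.all(np.abs(pts.mean(axis=0)) < 0.02)

    def test_same_seed_same_stream(self, icosphere):
        a = cldh._sample_surface(icosphere, 50, np.random.default_rng(5))
        b = cldh._sample_surface(icosphere, 50, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestCastChords:
    def test_convex_chords_equal_pair_distances(self, icosphere):
        # on a convex mesh every ray yields exactly the sampled pair
        lengths = cldh.cast_chords(icosphere, 200, np.random.default_rng(7),
                                   batch=256)
        pairs = cldh._sample_surface(
            icosphere, 2 * 256, np.random.default_rng(7)).reshape(256, 2, 3)
        direct = np.linalg.norm(pairs[:, 1] - pairs[:, 0], axis=1)
        np.testing.assert_allclose(lengths[:200], direct[:200], atol=1e-9)

    def test_sphere_mean_chord_length(self, icosphere):
        lengths = cldh.cast_chords(icosphere, 8000, np.random.default_rng(1))
        assert lengths.mean() == pytest.approx(4.0 / 3.0, rel=0.02)

    def test_sphere_chord_cdf_matches_analytic_law(self, icosphere):
        # linear density p(l) = l/2 on [0, 2] => CDF l^2/4
        lengths = np.sort(cldh.cast_chords(icosphere, 8000,
                                           np.random.default_rng(2)))
        emp = np.arange(1, len(lengths) + 1) / len(lengths)
        ks = np.max(np.abs(emp - lengths**2 / 4.0))
        assert ks < 0.02

    def test_open_mesh_rejected(self):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]])
        with pytest.raises(ValueError):
            cldh.cast_chords(tri, 10, np.random.default_rng(0))

    def test_agrees_with_plane_solve_oracle(self, mushroom_spine):
        # independent intersector on a non-convex mesh: per-triangle
        # plane-equation solve followed by a barycentric test, nothing
        # shared with the batched production path
        spine, _ = mushroom_spine
        mesh = spine.mesh
        rng = np.random.default_rng(9)
        pairs = cldh._sample_surface(mesh, 20, rng).reshape(10, 2, 3)
        diag = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
        tri = np.asarray(mesh.triangles)

        def oracle(origin, d):
            hits = []
            for a, b, c in tri:
                normal = np.cross(b - a, c - a)
                denom = normal @ d
                if abs(denom) < 1e-12:
                    continue
                t = (normal @ (a - origin)) / denom
                if t < 0:
                    continue
                p = origin + t * d
                # barycentric coordinates via least squares
                m = np.stack([b - a, c - a], axis=1)
                uv, *_ = np.linalg.lstsq(m, p - a, rcond=None)
                if uv[0] >= -1e-9 and uv[1] >= -1e-9 and uv.sum() <= 1 + 1e-9:
                    hits.append(t)
            return np.unique(np.round(np.sort(hits), 9))

        for p1, p2 in pairs:
            d = p2 - p1
            d /= np.linalg.norm(d)
            origin = p1 - d * diag
            ts = cldh._ray_mesh_ts(origin[None], d[None], tri)[0]
            ts = np.unique(np.round(np.sort(ts), 9))
            ref = oracle(origin, d)
            assert len(ts) == len(ref)
            np.testing.assert_allclose(ts, ref, atol=1e-6)


class TestBuildCldh:
    def test_identical_lengths_last_bin(self):
        h = cldh.build_cldh(np.full(100, 3.7), n_bins=100)
        assert h.bins[-1] == pytest.approx(1.0)
        assert h.max_length == pytest.approx(3.7)

    def test_bins_sum_to_one(self, rng):
        h = cldh.build_cldh(rng.random(1000) + 0.1)
        assert h.bins.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cldh.build_cldh([])

    def test_scale_invariance_same_seed(self, mushroom_spine):
        spine, _ = mushroom_spine
        h1 = cldh.compute_cldh(spine.mesh, n_chords=5000, seed=4)
        scaled = spine.mesh.copy()
        scaled.vertices = scaled.vertices * 3.0
        h2 = cldh.compute_cldh(scaled, n_chords=5000, seed=4)
        assert cldh.jensen_shannon_distance(h1, h2) < 0.02
        assert h2.max_length == pytest.approx(3 * h1.max_length, rel=1e-9)

    def test_rigid_invariance_same_seed(self, mushroom_spine):
        spine, _ = mushroom_spine
        h1 = cldh.compute_cldh(spine.mesh, n_chords=5000, seed=4)
        rng = np.random.default_rng(13)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = spine.mesh.copy()
        moved.vertices = moved.vertices @ q.T + rng.normal(size=3)
        h2 = cldh.compute_cldh(moved, n_chords=5000, seed=4)
        assert cldh.jensen_shannon_distance(h1, h2) < 0.02


class TestJensenShannon:
    def test_identity(self, rng):
        p = rng.random(100)
        p /= p.sum()
        assert cldh.jensen_shannon_distance(p, p) == 0.0

    def test_disjoint_is_one(self):
        assert cldh.jensen_shannon_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(10):
            p, q = rng.random(50), rng.random(50)
            p /= p.sum()
            q /= q.sum()
            assert cldh.jensen_shannon_distance(p, q) == pytest.approx(
                cldh.jensen_shannon_distance(q, p), abs=1e-12)

    def test_matches_scipy_base2(self, rng):
        from scipy.spatial.distance import jensenshannon

        for _ in range(20):
            p, q = rng.random(40), rng.random(40)
            p /= p.sum()
            q /= q.sum()
            assert cldh.jensen_shannon_distance(p, q) == pytest.approx(
                float(jensenshannon(p, q, base=2)), abs=1e-10)

    def test_triangle_inequality(self, rng):
        for _ in range(100):
            p, q, r = (rng.random(30) for _ in range(3))
            p, q, r = p / p.sum(), q / q.sum(), r / r.sum()
            d = cldh.jensen_shannon_distance
            assert d(p, r) <= d(p, q) + d(q, r) + 1e-12

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            cldh.jensen_shannon_distance([1.0], [0.5, 0.5])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            cldh.jensen_shannon_distance([0.5, 0.2], [0.5, 0.5])


class TestPairwiseAndConvergence:
    def test_duplicate_pair_zero_matrix(self, rng):
        p = rng.random(20)
        p /= p.sum()
        m = cldh.pairwise_distance_matrix([p, p])
        np.testing.assert_allclose(m, 0.0)

    def test_matrix_matches_scalar(self, rng):
        hs = []
        for _ in range(4):
            p = rng.random(25)
            hs.append(p / p.sum())
        m = cldh.pairwise_distance_matrix(hs)
        assert m.shape == (4, 4)
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        for i in range(4):
            for j in range(4):
                assert m[i, j] == pytest.approx(
                    cldh.jensen_shannon_distance(hs[i], hs[j]))

    def test_distinct_spines_have_positive_distances(self):
        from spinemorph import synthetic

        rng = np.random.default_rng(21)
        hists = []
        for arch in ("mushroom", "thin", "stubby", "filopodia"):
            spine, _ = synthetic.make_spine_mesh(
                synthetic.sample_spec(arch, rng), rng)
            hists.append(cldh.compute_cldh(spine.mesh, n_chords=3000, seed=1))
        m = cldh.pairwise_distance_matrix(hists)
        off = m[~np.eye(len(hists), dtype=bool)]
        assert (off > 0).all()

    def test_convergence_curve_decreases(self, mushroom_spine):
        spine, _ = mushroom_spine
        grid, means = cldh.convergence_curve(
            spine.mesh, [500, 8000], reps=2, rng=np.random.default_rng(2))
        assert means[-1] < means[0]

    def test_invalid_grid_rejected(self, mushroom_spine):
        spine, _ = mushroom_spine
        with pytest.raises(ValueError):
            cldh.convergence_curve(spine.mesh, [1000, 1000], reps=2)


class TestJSDHypothesis:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=50),
           st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_and_symmetry_on_arbitrary_histograms(self, raw, data):
        from hypothesis import strategies as st

        p = np.asarray(raw)
        p = p / p.sum()
        q_raw = data.draw(st.lists(st.floats(0.01, 10.0), min_size=len(p),
                                   max_size=len(p)))
        q = np.asarray(q_raw)
        q = q / q.sum()
        d = cldh.jensen_shannon_distance(p, q)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(cldh.jensen_shannon_distance(q, p),
                                  abs=1e-12)
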