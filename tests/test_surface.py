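"""Surface GLM, cluster extraction and Freedman-Lane permutation inference."""

import numpy as np
import pytest
import statsmodels.api as sm

from mtlpath.simulate import MeshSpec, generate_surface_dataset
from mtlpath.surface import (SurfaceDataset, SurfaceGLM, corrected_p,
                             extract_clusters, fit_pointwise,
                             freedman_lane_null, make_grid_mesh,
                             triangle_areas, vertex_adjacency, ClusterResult)


def small_dataset(n=30, nx=8, ny=8, effect=0.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    spec = MeshSpec(nx=nx, ny=ny, effect_mm_per_sd=effect,
                    cluster_radius_mm=2.0, noise_sd=noise)
    return generate_surface_dataset(n, spec, rng.normal(size=n), seed=seed + 1)


class TestPointwiseFit:
    def test_matches_per_vertex_regression_oracle(self):
        data, _ = small_dataset(n=25, nx=5, ny=10, effect=0.4, seed=3)
        tmap = fit_pointwise(data)
        ci = data.contrast_index
        for v in range(data.thickness.shape[1]):
            res = sm.OLS(data.thickness[:, v], data.design).fit()
            assert tmap[v] == pytest.approx(res.tvalues[ci], abs=1e-10)

    def test_single_vertex_equals_scalar_ols_t(self):
        data, _ = small_dataset(n=40, seed=5)
        tmap = fit_pointwise(data)
        v = 17
        res = sm.OLS(data.thickness[:, v], data.design).fit()
        assert tmap[v] == pytest.approx(res.tvalues[data.contrast_index])

    def test_null_tmap_moments_match_t_distribution(self):
        data, _ = small_dataset(n=40, nx=40, ny=40, effect=0.0, seed=7)
        tmap = fit_pointwise(data)
        df = data.thickness.shape[0] - data.design.shape[1]
        assert abs(tmap.mean()) < 0.05
        assert tmap.var() == pytest.approx(df / (df - 2), rel=0.1)

    def test_zero_residual_variance_gives_zero_t(self):
        vertices, triangles = make_grid_mesh(3, 3)
        n = 10
        thickness = np.full((n, 9), 2.5)  # constant: zero residual variance
        rng = np.random.default_rng(0)
        design = np.column_stack([np.ones(n), rng.normal(size=n)])
        data = SurfaceDataset(vertices, triangles, thickness, design,
                              ["const", "x"], "x")
        assert np.all(fit_pointwise(data) == 0.0)

    def test_rank_deficient_design_rejected(self):
        vertices, triangles = make_grid_mesh(3, 3)
        design = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            SurfaceDataset(vertices, triangles, np.zeros((10, 9)), design,
                           ["const", "dup"], 1)


class TestClusterExtraction:
    def test_no_suprathreshold_vertices_gives_empty_list(self):
        vertices, triangles = make_grid_mesh(4, 4)
        assert extract_clusters(np.zeros(16), vertices, triangles) == []

    def test_isolated_triangle_area_half(self):
        # one unit right triangle, all three vertices suprathreshold
        vertices = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        triangles = np.array([[0, 1, 2]])
        tmap = np.array([3.0, 3.0, 3.0])
        for fractional in (True, False):
            (cl,) = extract_clusters(tmap, vertices, triangles, 2.0,
                                     direction=1, fractional_area=fractional)
            assert cl.area_mm2 == pytest.approx(0.5)

    def test_two_planted_patches_match_flood_fill_oracle(self):
        import networkx as nx
        vertices, triangles = make_grid_mesh(12, 12)
        tmap = np.zeros(144)
        patch_a = [0, 1, 12, 13]
        patch_b = [100, 101, 112]
        tmap[patch_a] = -3.0
        tmap[patch_b] = -4.0
        clusters = extract_clusters(tmap, vertices, triangles, 2.0, -1)
        assert len(clusters) == 2
        g = nx.Graph()
        for tri in triangles:
            g.add_edges_from([(tri[0], tri[1]), (tri[1], tri[2]),
                              (tri[0], tri[2])])
        sub = g.subgraph(np.flatnonzero(-tmap > 2.0))
        oracle = {frozenset(c) for c in nx.connected_components(sub)}
        assert {frozenset(c.vertex_ids) for c in clusters} == oracle

    def test_total_suprathreshold_area_conserved(self):
        rng = np.random.default_rng(2)
        vertices, triangles = make_grid_mesh(16, 16)
        tmap = rng.normal(size=256)
        clusters = extract_clusters(tmap, vertices, triangles, 1.0, 1)
        from mtlpath.surface import vertex_area_shares
        shares = vertex_area_shares(vertices, triangles)
        total = shares[tmap > 1.0].sum()
        assert sum(c.area_mm2 for c in clusters) == pytest.approx(total)

    def test_area_invariance_under_rigid_motion_and_scaling(self):
        rng = np.random.default_rng(4)
        vertices, triangles = make_grid_mesh(10, 10)
        tmap = rng.normal(size=100)
        base = extract_clusters(tmap, vertices, triangles, 1.0, 1)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = vertices @ rot.T + np.array([5.0, -3.0, 2.0])
        rigid = extract_clusters(tmap, moved, triangles, 1.0, 1)
        for b, r in zip(base, rigid):
            assert r.area_mm2 == pytest.approx(b.area_mm2, rel=1e-10)
        scaled = extract_clusters(tmap, 2.0 * vertices, triangles, 1.0, 1)
        for b, s in zip(base, scaled):
            assert s.area_mm2 == pytest.approx(4.0 * b.area_mm2, rel=1e-10)

    def test_peak_t_is_extreme_in_contrast_direction(self):
        vertices, triangles = make_grid_mesh(5, 5)
        tmap = np.zeros(25)
        tmap[[6, 7, 8]] = [-2.5, -4.0, -3.0]
        (cl,) = extract_clusters(tmap, vertices, triangles, 2.0, -1)
        assert cl.peak_t == -4.0


class TestFreedmanLane:
    def test_intercept_only_equals_naive_permutation(self):
        # with no nuisance beyond the intercept, the two-step procedure
        # reduces to naive row permutation of the data (same seed stream)
        rng = np.random.default_rng(6)
        vertices, triangles = make_grid_mesh(8, 8)
        n = 24
        thickness = rng.normal(2.5, 0.3, size=(n, 64))
        design = np.column_stack([np.ones(n), rng.normal(size=n)])
        data = SurfaceDataset(vertices, triangles, thickness, design,
                              ["const", "x"], "x", direction=1)
        null_fl = freedman_lane_null(data, 50, threshold=2.0, seed=9)

        from mtlpath.surface import _PointwiseOLS, _max_cluster_area
        from mtlpath.surface import vertex_area_shares
        adj = vertex_adjacency(64, triangles)
        shares = vertex_area_shares(vertices, triangles)
        ols = _PointwiseOLS(design, 1)
        rng2 = np.random.default_rng(9)
        naive = np.array([
            _max_cluster_area(ols.tmap(thickness[rng2.permutation(n)]),
                              shares, adj, 2.0, 1)
            for _ in range(50)])
        assert np.allclose(null_fl, naive, atol=1e-10)

    def test_null_distribution_mass_at_zero_for_high_threshold(self):
        data, _ = small_dataset(n=20, effect=0.0, seed=11)
        null = freedman_lane_null(data, 40, threshold=6.0, seed=1)
        assert (null == 0.0).mean() > 0.5

    def test_deterministic_given_seed(self):
        data, _ = small_dataset(n=20, seed=12)
        a = freedman_lane_null(data, 30, seed=5)
        b = freedman_lane_null(data, 30, seed=5)
        assert np.array_equal(a, b)

    def test_planted_effect_exceeds_all_null_maxima(self):
        # a spatially tapered (Gaussian-profile) deficit: the observed
        # cluster spans the broad tail, which even a rare severity-aligned
        # permutation cannot reproduce
        rng = np.random.default_rng(13)
        nx = ny = 24
        vertices, triangles = make_grid_mesh(nx, ny)
        n = 60
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)
        d2 = ((vertices[:, 0] - 11.5) ** 2 + (vertices[:, 1] - 11.5) ** 2)
        profile = 0.9 * np.exp(-d2 / (2 * 4.0**2))
        thickness = (2.5 - np.outer(z, profile)
                     + rng.normal(0, 0.25, size=(n, nx * ny)))
        design = np.column_stack([np.ones(n), z, rng.normal(size=n)])
        data = SurfaceDataset(vertices, triangles, thickness, design,
                              ["const", "pathology", "age"], "pathology")
        tmap = fit_pointwise(data)
        observed = extract_clusters(tmap, data.vertices, data.triangles)
        null = freedman_lane_null(data, 500, seed=3)
        assert observed[0].area_mm2 > null.max()

    def test_invalid_n_perm_rejected(self):
        data, _ = small_dataset(n=20, seed=14)
        with pytest.raises(ValueError):
            freedman_lane_null(data, 0)


class TestCorrectedP:
    def test_counting_rule_without_ties(self):
        null = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mk = lambda a: ClusterResult(np.array([0]), a, 3.0)  # noqa: E731
        assert corrected_p([mk(10.0)], null)[0].p_corrected == 0.0
        assert corrected_p([mk(0.5)], null)[0].p_corrected == 1.0
        assert corrected_p([mk(3.5)], null)[0].p_corrected == pytest.approx(2 / 5)

    def test_tied_null_maxima_counted_half_by_default(self):
        null = np.array([1.0, 2.0, 2.0, 3.0])
        cl = ClusterResult(np.array([0]), 2.0, 3.0)
        assert corrected_p([cl], null)[0].p_corrected == pytest.approx(
            (1 + 0.5 * 2) / 4)
        assert corrected_p([cl], null,
                           ties="strict")[0].p_corrected == pytest.approx(1 / 4)

    def test_smoothed_estimate_never_zero(self):
        null = np.arange(1.0, 11.0)
        big = ClusterResult(np.array([0]), 99.0, 3.0)
        assert corrected_p([big], null, smoothing=True)[0].p_corrected == \
            pytest.approx(1 / 11)

    def test_matches_brute_force_counting(self, rng):
        null = rng.exponential(2.0, 200)
        areas = rng.exponential(2.0, 10)
        clusters = [ClusterResult(np.array([0]), a, 2.5) for a in areas]
        out = corrected_p(clusters, null)
        for cl, a in zip(out, areas):
            assert cl.p_corrected == pytest.approx(
                sum(x > a for x in null) / 200)


class TestSurfaceGLMEndToEnd:
    def test_planted_cluster_detected_with_high_overlap(self):
        spec = MeshSpec(nx=24, ny=24, effect_mm_per_sd=0.8,
                        cluster_radius_mm=4.0, noise_sd=0.25)
        rng = np.random.default_rng(17)
        data, planted = generate_surface_dataset(60, spec,
                                                 rng.normal(size=60), seed=18)
        res = SurfaceGLM(data).fit(n_perm=300, seed=19)
        top = res.clusters[0]
        assert top.p_corrected < 0.05
        inter = np.intersect1d(top.vertex_ids, planted).size
        union = len(top.vertex_ids) + planted.size - inter
        assert inter / union > 0.5

    def test_noise_free_strong_effect_recovers_planted_set_exactly(self):
        spec = MeshSpec(nx=16, ny=16, effect_mm_per_sd=1.0,
                        cluster_radius_mm=3.0, noise_sd=0.0)
        rng = np.random.default_rng(20)
        data, planted = generate_surface_dataset(30, spec,
                                                 rng.normal(size=30), seed=21)
        tmap = fit_pointwise(data)
        (cl,) = extract_clusters(tmap, data.vertices, data.triangles)
        assert np.array_equal(np.sort(cl.vertex_ids), np.sort(planted))

    def test_summary_reports_clusters(self):
        data, _ = small_dataset(n=30, effect=1.0, noise=0.2, seed=23)
        res = SurfaceGLM(data).fit(n_perm=50, seed=1)
        text = res.summary()
        assert "cluster threshold" in text and "pathology" in text


class TestMeshValidation:
    def test_non_manifold_mesh_rejected(self):
        vertices = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                             [0.5, 0.5, 1]], dtype=float)
        triangles = np.array([[0, 1, 2], [1, 2, 3], [1, 2, 4]])  # shared edge x3
        with pytest.raises(ValueError, match="manifold"):
            SurfaceDataset(vertices, triangles, np.zeros((10, 5)),
                           np.column_stack([np.ones(10), np.arange(10.0)]),
                           ["const", "x"], "x")

    def test_triangle_areas_of_grid_sum_to_domain_area(self):
        vertices, triangles = make_grid_mesh(7, 5, spacing_mm=2.0)
        assert triangle_areas(vertices, triangles).sum() == pytest.approx(
            (6 * 2.0) * (4 * 2.0))
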