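import math

import numpy as np
import pytest
from scipy.integrate import quad

from pinspect.geometry import (
    CollimatorParams,
    DetectorParams,
    HoleSpec,
    OrbitSpec,
    generate_orbit,
)
from pinspect.io_interfile import ImageVolume
from pinspect.system_matrix import (
    BinGrid,
    MatrixConfig,
    PinholeProjector,
    apply_doi,
    attenuation_factors,
    build_mask,
    compute_view_matrix,
    geometric_footprint,
    psf_kernel,
)

from conftest import make_detector, make_hole, make_projector

VIEW0 = generate_orbit(OrbitSpec(n_angles=1, initial_angle=0.0))[0]
BINS = BinGrid(n_axial=49, n_trans=49, bin_size=0.75)
HOLE = make_hole(diameter=1.0, distance=24.0)


def footprint_stats(fp, bins):
    w = np.array([wt for _, wt in fp])
    u = np.array([(it - (bins.n_trans - 1) / 2) * bins.bin_size for (_, it), _ in fp])
    v = np.array([(ia - (bins.n_axial - 1) / 2) * bins.bin_size for (ia, _), _ in fp])
    total = w.sum()
    return total, (u @ w / total, v @ w / total)


class TestPsfKernel:
    def test_unit_sum(self):
        for fwhm, binsize, sub, nsig in [(1.8, 0.5, 1, 2.0), (3.2, 0.75, 4, 3.5), (0.4, 1.0, 2, 2.0)]:
            k = psf_kernel(fwhm, binsize, sub, nsig)
            assert k.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(k >= 0)

    def test_zero_fwhm_is_delta(self):
        np.testing.assert_array_equal(psf_kernel(0.0, 0.5), [[1.0]])

    def test_centre_bin_matches_quadrature(self):
        # FWHM = 2.355 * bin -> sigma == bin; large n_sigma so truncation is negligible
        binsize = 0.5
        fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * binsize
        sigma = binsize
        k = psf_kernel(fwhm, binsize, subsampling=4, n_sigma=8.0)
        centre = k[k.shape[0] // 2, k.shape[1] // 2]
        gauss = lambda t: math.exp(-t * t / (2 * sigma * sigma)) / (sigma * math.sqrt(2 * math.pi))
        one_d, _ = quad(gauss, -binsize / 2, binsize / 2)
        assert centre == pytest.approx(one_d**2, rel=1e-6)

    def test_truncation_limits_support(self):
        k = psf_kernel(2.355, 1.0, subsampling=1, n_sigma=1.0)  # sigma = 1 mm
        assert k.shape[0] <= 3  # bins beyond 1 sigma are dropped

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            psf_kernel(1.0, -1.0)
        with pytest.raises(ValueError):
            psf_kernel(1.0, 1.0, subsampling=0)


class TestGeometricFootprint:
    def test_on_axis_magnification_closed_form(self):
        # source on the hole axis at distance d; detection plane f behind the hole
        d, f = 24.0, 36.0
        fp = geometric_footprint((0.0, 0.0, 0.0), HOLE, VIEW0, BINS,
                                 plane_distance=60.0, raster_supersampling=32)
        total, (cu, cv) = footprint_stats(fp, BINS)
        w_expected = HOLE.area / (4 * math.pi * d * d)
        assert total == pytest.approx(w_expected, rel=5e-3)
        assert abs(cu) < 0.1 * BINS.bin_size
        assert abs(cv) < 0.1 * BINS.bin_size
        # equivalent-area diameter of the footprint: a * (d + f) / d
        coverage_area = (total / w_expected) * HOLE.area * ((d + f) / d) ** 2
        diameter = 2.0 * math.sqrt(coverage_area / math.pi)
        assert diameter == pytest.approx(1.0 * (d + f) / d, abs=0.1 * BINS.bin_size)

    def test_weights_match_bruteforce_pixel_overlap(self):
        # independent oracle: dense-subgrid coverage of the projected disc
        d, f = 24.0, 36.0
        rho = 0.5 * (d + f) / d
        fp = geometric_footprint((0.0, 0.0, 0.0), HOLE, VIEW0, BINS,
                                 plane_distance=60.0, raster_supersampling=32)
        w_geom = HOLE.area / (4 * math.pi * d * d)
        b = BINS.bin_size
        for (ia, it), w in fp:
            uc = (it - (BINS.n_trans - 1) / 2) * b
            vc = (ia - (BINS.n_axial - 1) / 2) * b
            n = 201
            uu = uc + (np.arange(n) + 0.5) / n * b - b / 2
            vv = vc + (np.arange(n) + 0.5) / n * b - b / 2
            inside = (uu[None, :] ** 2 + vv[:, None] ** 2) <= rho * rho
            oracle = w_geom * inside.mean() * b * b / (math.pi * rho * rho)
            assert w == pytest.approx(oracle, rel=0.05, abs=1e-3 * w_geom)

    def test_outside_acceptance_cone_empty(self):
        hole = make_hole(acceptance=10.0)
        fp = geometric_footprint((15.0, 0.0, 0.0), hole, VIEW0, BINS, plane_distance=60.0)
        assert fp == []

    def test_inverse_square_law(self):
        fp1 = geometric_footprint((0.0, 12.0, 0.0), HOLE, VIEW0, BINS,
                                  plane_distance=60.0, raster_supersampling=16)
        fp2 = geometric_footprint((0.0, 0.0, 0.0), HOLE, VIEW0, BINS,
                                  plane_distance=60.0, raster_supersampling=16)
        t1, _ = footprint_stats(fp1, BINS)  # r = 12
        t2, _ = footprint_stats(fp2, BINS)  # r = 24
        assert t2 / t1 == pytest.approx(0.25, rel=0.02)

    def test_off_axis_centroids(self):
        d, f = 24.0 - (-6.0), 60.0 - 24.0
        for sx, sz in [(5.0, 3.0), (-4.0, -2.0), (0.0, 7.0)]:
            fp = geometric_footprint((sx, -6.0, sz), HOLE, VIEW0, BINS,
                                     plane_distance=60.0, raster_supersampling=32)
            _, (cu, cv) = footprint_stats(fp, BINS)
            assert cu == pytest.approx(-sx * f / d, abs=0.1 * BINS.bin_size)
            assert cv == pytest.approx(-sz * f / d, abs=0.1 * BINS.bin_size)

    def test_voxel_at_hole_centre_raises(self):
        with pytest.raises(ValueError, match="coincident"):
            geometric_footprint(HOLE.position, HOLE, VIEW0, BINS, plane_distance=60.0)


class TestApplyDoi:
    def test_normal_incidence_total_weight(self):
        det = make_detector(OrbitSpec(n_angles=1), thickness=6.0, mu_c=0.25, face=57.0)
        fp = apply_doi((0.0, 0.0, 0.0), HOLE, VIEW0, BINS, det,
                       sampling_interval=0.5, raster_supersampling=32)
        total = sum(w for _, w in fp)
        w_geom = HOLE.area / (4 * math.pi * 24.0**2)
        assert total == pytest.approx((1 - math.exp(-0.25 * 6.0)) * w_geom, rel=0.01)
        _, (cu, cv) = footprint_stats(fp, BINS)
        assert abs(cu) < 1e-6 and abs(cv) < 1e-6  # no lateral shift on axis

    def test_zero_thickness_equals_geometric_at_face(self):
        det = make_detector(OrbitSpec(n_angles=1), thickness=0.0, mu_c=0.25, face=60.0)
        fp = apply_doi((1.0, -3.0, 2.0), HOLE, VIEW0, BINS, det, sampling_interval=0.5)
        ref = geometric_footprint((1.0, -3.0, 2.0), HOLE, VIEW0, BINS, plane_distance=60.0)
        assert fp == ref

    def test_zero_crystal_attenuation_falls_back_to_middepth(self, caplog):
        import logging

        det = make_detector(OrbitSpec(n_angles=1), thickness=6.0, mu_c=0.0, face=57.0)
        with caplog.at_level(logging.WARNING):
            fp = apply_doi((1.0, -3.0, 2.0), HOLE, VIEW0, BINS, det, sampling_interval=0.5)
        ref = geometric_footprint((1.0, -3.0, 2.0), HOLE, VIEW0, BINS, plane_distance=60.0)
        assert fp == ref
        assert any("mid-depth" in r.message for r in caplog.records)

    def test_doi_disabled_uses_face_plus_half_thickness(self, fixture_problem):
        # two detectors: (face 57, T 6, DOI off) vs (face 60, T 0): identical matrices
        orbit = fixture_problem["orbit"]
        grid = fixture_problem["grid"]
        coll = fixture_problem["collimator"]
        bins = fixture_problem["bins"]
        det_a = make_detector(orbit, thickness=6.0, face=57.0)
        det_b = make_detector(orbit, thickness=0.0, face=60.0)
        cfg = MatrixConfig()
        view = generate_orbit(orbit)[0]
        m_a = compute_view_matrix(view, grid, det_a, coll, cfg, bins)
        m_b = compute_view_matrix(view, grid, det_b, coll, cfg, bins)
        assert (m_a.matrix != m_b.matrix).nnz == 0


class TestAttenuationFactors:
    @pytest.fixture
    def slab_map(self):
        mu = np.zeros((16, 16, 16))
        mu[:, 4:12, :] = 0.02  # 8 mm slab along y
        return ImageVolume(mu, voxel_size=1.0)

    def test_zero_mu_gives_unity(self):
        amap = ImageVolume(np.zeros((8, 8, 8)), voxel_size=1.0)
        f = attenuation_factors((0.0, 0.0, 0.0), HOLE, VIEW0, amap, "simple")
        assert f == 1.0

    def test_uniform_slab_closed_form(self, slab_map):
        rng = np.random.default_rng(11)
        h = np.array(HOLE.position)
        for _ in range(50):
            p = np.array([rng.uniform(-6, 6), rng.uniform(-7, -4.5), rng.uniform(-5, 5)])
            f = attenuation_factors(tuple(p), HOLE, VIEW0, slab_map, "simple")
            d = h - p
            t1, t2 = (4.0 - p[1]) / d[1], (-4.0 - p[1]) / d[1]
            t1, t2 = max(0.0, min(t1, t2)), min(1.0, max(t1, t2))
            chord = max(0.0, t2 - t1) * float(np.linalg.norm(d))
            assert f == pytest.approx(math.exp(-0.02 * chord), rel=0.005)

    def test_point_footprint_full_equals_simple(self, slab_map):
        # geometry with the projection landing exactly on a bin centre
        bins = BinGrid(n_axial=49, n_trans=49, bin_size=0.75)
        tiny = make_hole(diameter=0.01)
        fp = geometric_footprint((0.0, 0.0, 0.0), tiny, VIEW0, bins, plane_distance=60.0)
        assert len(fp) == 1 and fp[0][0] == (24, 24)
        simple = attenuation_factors((0.0, 0.0, 0.0), tiny, VIEW0, slab_map, "simple")
        full = attenuation_factors((0.0, 0.0, 0.0), tiny, VIEW0, slab_map, "full",
                                   footprint=fp, bins=bins, plane_distance=60.0)
        assert full[(24, 24)] == simple

    def test_negative_mu_raises(self):
        amap = ImageVolume(np.full((4, 4, 4), -0.01), voxel_size=1.0)
        with pytest.raises(ValueError, match="negative"):
            attenuation_factors((0.0, 0.0, 0.0), HOLE, VIEW0, amap, "simple")

    def test_bad_mode_raises(self, slab_map):
        with pytest.raises(ValueError):
            attenuation_factors((0.0, 0.0, 0.0), HOLE, VIEW0, slab_map, "off")


class TestBuildMask:
    @pytest.fixture
    def grid(self):
        return ImageVolume(np.zeros((8, 64, 64)), voxel_size=0.75)

    def test_cylinder_radius_23(self, grid):
        mask = build_mask("cylinder", grid, object_radius=23.0)
        x, y, _ = grid.axis_coords()
        expected = (x[None, None, :] ** 2 + y[None, :, None] ** 2) <= 23.0**2
        np.testing.assert_array_equal(mask.include, np.broadcast_to(expected, grid.shape))

    def test_radius_larger_than_grid_all_true(self, grid):
        mask = build_mask("cylinder", grid, object_radius=1000.0)
        assert mask.include.all()

    def test_attenuation_map_cylinder_equals_cylinder_mode(self, grid):
        from pinspect.phantoms import voxelize_cylinder

        occ = voxelize_cylinder(grid, (0.0, 0.0), 34.0, -100.0, 100.0, supersample=1)
        amap = grid.like(0.0151 * occ)
        via_map = build_mask("attenuation_map", grid, atten_map=amap)
        via_cyl = build_mask("cylinder", grid, object_radius=17.0)
        np.testing.assert_array_equal(via_map.include, via_cyl.include)

    def test_mask_beyond_object_radius_errors(self, grid):
        mu = np.zeros(grid.shape)
        mu[:, :, :] = 0.01  # object fills the grid, far beyond r = 5
        amap = grid.like(mu)
        with pytest.raises(ValueError, match="object radius"):
            build_mask("attenuation_map", grid, object_radius=5.0, atten_map=amap)

    def test_file_mask(self, grid, tmp_path):
        from pinspect.io_interfile import write_image_interfile

        mask_vol = grid.like((np.arange(grid.voxels.size).reshape(grid.shape) % 7 == 0) * 1.0)
        path = tmp_path / "mask.hv"
        write_image_interfile(mask_vol, path)
        mask = build_mask("file", grid, mask_file=str(path))
        np.testing.assert_array_equal(mask.include, mask_vol.voxels > 0)

    def test_cylinder_requires_radius(self, grid):
        with pytest.raises(ValueError):
            build_mask("cylinder", grid)


class TestComputeViewMatrix:
    def test_composition_identity_single_voxel(self, fixture_problem):
        # no corrections, one unmasked voxel: identical to the bare footprint
        orbit = fixture_problem["orbit"]
        det = make_detector(orbit, thickness=0.0, face=60.0)
        coll = fixture_problem["collimator"]
        bins = fixture_problem["bins"]
        grid = fixture_problem["grid"]
        from pinspect.system_matrix import VoxelMask

        include = np.zeros(grid.shape, dtype=bool)
        include[8, 9, 7] = True
        view = generate_orbit(orbit)[0]
        smv = compute_view_matrix(view, grid, det, coll, MatrixConfig(), bins,
                                  mask=VoxelMask(include))
        x, y, z = grid.axis_coords()
        centre = (x[7], y[9], z[8])
        fp = geometric_footprint(centre, coll.holes[0], view, bins, plane_distance=60.0)
        assert smv.entries_for_voxel((8, 9, 7)) == fp
        # masked voxels have empty columns
        assert smv.matrix.nnz == len(fp)

    def test_psf_conserves_per_voxel_weight(self, fixture_problem):
        problem = fixture_problem
        p_plain = make_projector(problem)
        p_psf = make_projector(problem, psf_enabled=True, psf_n_sigma=6.0)
        m0 = p_plain.view_matrix(0).matrix
        m1 = p_psf.view_matrix(0).matrix
        col0 = np.asarray(m0.sum(axis=0)).ravel()
        col1 = np.asarray(m1.sum(axis=0)).ravel()
        # central voxels: footprints (plus PSF tails) stay fully on the detector
        keep = np.zeros(problem["grid"].shape, dtype=bool)
        keep[6:10, 6:10, 6:10] = True
        keep = keep.ravel() & (col0 > 0)
        assert keep.any()
        np.testing.assert_allclose(col1[keep], col0[keep], rtol=1e-6)

    def test_all_corrections_finite_nonnegative(self, fixture_problem):
        problem = fixture_problem
        mu = 0.01 * np.ones(problem["grid"].shape)
        amap = problem["grid"].like(mu)
        p = make_projector(
            problem, atten_map=amap,
            psf_enabled=True, doi_enabled=True, attenuation="full",
            sampling_interval=2.0, mask="cylinder", object_radius=10.0,
        )
        m = p.view_matrix(0).matrix
        assert np.all(np.isfinite(m.data))
        assert np.all(m.data >= 0)
        # masked-out voxels (outside the cylinder) have empty columns
        outside = ~p.mask.include.ravel()
        nnz_per_col = np.diff(m.tocsc().indptr)
        assert nnz_per_col[outside].sum() == 0

    def test_min_weight_truncation(self, fixture_problem):
        p_all = make_projector(fixture_problem, min_weight=0.0)
        m_all = p_all.view_matrix(0).matrix
        threshold = float(np.percentile(m_all.data, 40))
        p_cut = make_projector(fixture_problem, min_weight=threshold)
        m_cut = p_cut.view_matrix(0).matrix
        assert m_cut.nnz < m_all.nnz
        assert np.all(m_cut.data >= threshold)

    def test_attenuation_requires_map(self, fixture_problem):
        with pytest.raises(ValueError, match="attenuation"):
            make_projector(fixture_problem, attenuation="simple")

    def test_multi_hole_weights_sum(self, fixture_problem):
        problem = dict(fixture_problem)
        h1 = make_hole()
        h2 = HoleSpec(position=(0.0, 24.0, 3.0), size=1.0, acceptance_angle=50.0)
        problem["collimator"] = CollimatorParams(radius_of_rotation=24.0, holes=[h1, h2])
        p_both = make_projector(problem)
        problem1 = dict(problem)
        problem1["collimator"] = CollimatorParams(radius_of_rotation=24.0, holes=[h1])
        problem2 = dict(problem)
        problem2["collimator"] = CollimatorParams(radius_of_rotation=24.0, holes=[h2])
        m_both = p_both.view_matrix(0).matrix
        m_sum = make_projector(problem1).view_matrix(0).matrix + \
            make_projector(problem2).view_matrix(0).matrix
        assert abs(m_both - m_sum).max() < 1e-15


class TestProjectorOperators:
    def test_zero_image_zero_projection(self, fixture_problem):
        p = make_projector(fixture_problem)
        assert np.all(p.forward(np.zeros(fixture_problem["grid"].shape)) == 0)

    def test_linearity(self, fixture_problem):
        p = make_projector(fixture_problem)
        rng = np.random.default_rng(5)
        x1 = rng.uniform(size=fixture_problem["grid"].shape)
        x2 = rng.uniform(size=fixture_problem["grid"].shape)
        np.testing.assert_allclose(
            p.forward(x1 + x2), p.forward(x1) + p.forward(x2), rtol=1e-9, atol=1e-30
        )

    def test_adjoint_identity(self, fixture_problem):
        p = make_projector(fixture_problem)
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.uniform(size=fixture_problem["grid"].shape)
            y = rng.uniform(size=(p.n_views, p.bins.n_axial, p.bins.n_trans))
            lhs = float((p.forward(x) * y).sum())
            rhs = float((x * p.back(y)).sum())
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_one_hot_backprojection_is_matrix_column(self, fixture_problem):
        p = make_projector(fixture_problem)
        smv = p.view_matrix(0)
        bin_flat = int(smv.matrix.sum(axis=1).argmax())
        one_hot = np.zeros((1, p.bins.n_axial, p.bins.n_trans))
        one_hot[0, bin_flat // p.bins.n_trans, bin_flat % p.bins.n_trans] = 1.0
        bp = p.back(one_hot, [0]).ravel()
        row = np.asarray(smv.matrix.getrow(bin_flat).todense()).ravel()
        np.testing.assert_array_equal(bp, row)

    def test_zero_projection_zero_image(self, fixture_problem):
        p = make_projector(fixture_problem)
        y = np.zeros((p.n_views, p.bins.n_axial, p.bins.n_trans))
        assert np.all(p.back(y) == 0)

    def test_mode_equivalence_bit_identical(self, fixture_problem):
        rng = np.random.default_rng(7)
        x = rng.uniform(size=fixture_problem["grid"].shape)
        p_mem = make_projector(fixture_problem, keep_in_memory=True)
        p_fly = make_projector(fixture_problem, keep_in_memory=False)
        proj_mem = p_mem.forward(x)
        proj_fly = p_fly.forward(x)
        np.testing.assert_array_equal(proj_mem, proj_fly)
        assert p_fly._cache == {}  # per-angle mode releases every matrix

    def test_grid_mismatch_raises(self, fixture_problem):
        p = make_projector(fixture_problem)
        with pytest.raises(ValueError):
            p.forward(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            p.back(np.zeros((p.n_views, 3, 3)))

    def test_n_orbits_scales_weights(self, fixture_problem):
        problem = dict(fixture_problem)
        orbit1 = problem["orbit"]
        orbit3 = OrbitSpec(n_orbits=3, n_angles=orbit1.n_angles,
                           initial_angle=orbit1.initial_angle,
                           angular_increment=orbit1.angular_increment)
        problem3 = dict(problem)
        problem3["detector"] = make_detector(orbit3)
        rng = np.random.default_rng(8)
        x = rng.uniform(size=problem["grid"].shape)
        p1 = make_projector(problem)
        p3 = make_projector(problem3)
        np.testing.assert_allclose(p3.forward(x), 3.0 * p1.forward(x), rtol=1e-12)
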