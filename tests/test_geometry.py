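import numpy as np
import pytest

from cathcalib import geometry as geo


def make_geom(**kw):
    intr1 = geo.CameraIntrinsics(sid=1189.0, u0=255.5, v0=255.5)
    intr2 = geo.CameraIntrinsics(sid=1207.0, u0=255.5, v0=255.5)
    pose1 = geo.GantryPose(alpha=-22.9, beta=-27.6, sod=716.44)
    pose2 = geo.GantryPose(alpha=-103.8, beta=13.4, sod=750.0)
    return geo.build_biplane_geometry(intr1, intr2, pose1, pose2)


def random_scene_points(rng, n=50):
    """3D points near the camera-1 optical axis at plausible depth."""
    pts = rng.uniform(-20, 20, (n, 3))
    pts[:, 2] += 716.0
    return pts


class TestIntrinsics:
    def test_matrix_entries(self):
        k = geo.build_intrinsic_matrix(
            geo.CameraIntrinsics(sid=1000.0, pu=0.154, pv=0.154, skew=0.0, u0=512, v0=512)
        )
        assert k[0, 0] == pytest.approx(1000 / 0.154)
        assert k[1, 1] == pytest.approx(1000 / 0.154)
        assert k[0, 1] == 0.0
        assert k[0, 2] == 512 and k[1, 2] == 512
        assert k[2, 2] == 1.0
        assert np.count_nonzero(np.tril(k, -1)) == 0  # upper triangular

    def test_determinant_positive(self):
        k = geo.build_intrinsic_matrix(geo.CameraIntrinsics(sid=745.97))
        assert np.isfinite(k).all()
        assert np.linalg.det(k) == pytest.approx((745.97 / 0.154) ** 2, rel=1e-12)

    @pytest.mark.parametrize("sid,pu,pv", [(-1, 0.1, 0.1), (100, 0, 0.1), (100, 0.1, -2)])
    def test_invalid_parameters(self, sid, pu, pv):
        with pytest.raises(geo.GeometryError):
            geo.CameraIntrinsics(sid=sid, pu=pu, pv=pv)


class TestRotations:
    def test_zero_angles_identity(self):
        assert np.allclose(geo.pose_to_rotation(0, 0), np.eye(3))

    def test_pure_y_rotation(self):
        alpha = 37.0
        r = geo.pose_to_rotation(alpha, 0)
        t = np.deg2rad(alpha)
        expected = np.array(
            [[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]]
        )
        assert np.allclose(r, expected)

    @pytest.mark.parametrize("alpha,beta", [(-22.90, -27.60), (73.7, -26.2), (180, 90)])
    def test_orthonormality(self, alpha, beta):
        r = geo.pose_to_rotation(alpha, beta)
        assert np.linalg.norm(r.T @ r - np.eye(3)) < 1e-12
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_relative_pose_identity(self):
        p = geo.GantryPose(alpha=10, beta=5, sod=700)
        r, t = geo.relative_pose(p, p)
        assert np.allclose(r, np.eye(3))
        assert np.allclose(t, 0)

    def test_relative_pose_orthogonal_views(self):
        # closed form: pose1 frontal, pose2 rotated 90 deg about y
        sod = 700.0
        r, t = geo.relative_pose(
            geo.GantryPose(alpha=0, beta=0, sod=sod),
            geo.GantryPose(alpha=90, beta=0, sod=sod),
        )
        assert np.allclose(r, geo.pose_to_rotation(90, 0))
        # T = T2 - R T1 with T_j = (0,0,sod)
        expected = np.array([0, 0, sod]) - r @ np.array([0, 0, sod])
        assert np.allclose(t, expected)
        assert np.linalg.norm(t) == pytest.approx(sod * np.sqrt(2), rel=1e-12)


class TestProjectionTriangulation:
    def test_principal_point_projection(self):
        g = make_geom()
        q = geo.project_points(g.p1, np.array([[0.0, 0.0, 500.0]]))
        assert np.allclose(q, [[255.5, 255.5]])

    def test_projective_ray_invariance(self):
        g = make_geom()
        q1 = geo.project_points(g.p1, np.array([[3.0, -2.0, 400.0]]))
        q2 = geo.project_points(g.p1, np.array([[7.5, -5.0, 1000.0]]))
        assert np.allclose(q1, q2)

    def test_matches_metric_formula(self):
        # Eq-style check: u = (SID/pu) x/z + u0 for the canonical view
        rng = np.random.default_rng(3)
        intr = geo.CameraIntrinsics(sid=1100.0, u0=100.0, v0=200.0)
        k = geo.build_intrinsic_matrix(intr)
        p1 = k @ np.hstack([np.eye(3), np.zeros((3, 1))])
        pts = random_scene_points(rng, 20)
        q = geo.project_points(p1, pts)
        f = intr.sid / intr.pu
        expected = np.column_stack(
            [f * pts[:, 0] / pts[:, 2] + 100.0, f * pts[:, 1] / pts[:, 2] + 200.0]
        )
        assert np.allclose(q, expected, atol=1e-9)

    def test_zero_depth_rejected(self):
        g = make_geom()
        with pytest.raises(geo.GeometryError):
            geo.project_points(g.p1, np.array([[1.0, 1.0, 0.0]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_identity(self, seed):
        """project -> triangulate -> reproject is identity on noiseless scenes."""
        g = make_geom()
        rng = np.random.default_rng(seed)
        pts = random_scene_points(rng, 100)
        q1 = geo.project_points(g.p1, pts)
        q2 = geo.project_points(g.p2, pts)
        rec = geo.triangulate_many(g.p1, g.p2, q1, q2)
        assert np.abs(rec - pts).max() < 1e-8
        r1 = geo.project_points(g.p1, rec)
        r2 = geo.project_points(g.p2, rec)
        assert np.abs(r1 - q1).max() < 1e-6
        assert np.abs(r2 - q2).max() < 1e-6

    def test_identical_projections_ill_posed(self):
        g = make_geom()
        with pytest.raises(geo.GeometryError):
            geo.triangulate_many(g.p1, g.p1, [[100.0, 100.0]], [[100.0, 100.0]])

    def test_perturbed_point_error_split(self):
        """1-px perturbation in one view -> reprojection error <= 1 px per view.

        Oracle: the DLT solution cannot do worse than the midpoint-style
        bound where the whole discrepancy is assigned to one view.
        """
        g = make_geom()
        rng = np.random.default_rng(11)
        pts = random_scene_points(rng, 30)
        q1 = geo.project_points(g.p1, pts)
        q2 = geo.project_points(g.p2, pts) + np.array([1.0, 0.0])
        rec = geo.triangulate_many(g.p1, g.p2, q1, q2)
        e1 = np.linalg.norm(geo.project_points(g.p1, rec) - q1, axis=1)
        e2 = np.linalg.norm(geo.project_points(g.p2, rec) - q2, axis=1)
        assert (e1 <= 1.0 + 1e-6).all() and (e2 <= 1.0 + 1e-6).all()
        assert (e1 + e2 > 1e-3).all()  # the discrepancy cannot vanish


class TestEpipolar:
    def test_fundamental_rank_and_residual(self):
        g = make_geom()
        f = geo.fundamental_matrix(g)
        assert np.linalg.matrix_rank(f, tol=1e-10) == 2
        assert np.linalg.norm(f) == pytest.approx(1.0)
        rng = np.random.default_rng(5)
        pts = random_scene_points(rng, 50)
        q1 = geo.project_points(g.p1, pts)
        q2 = geo.project_points(g.p2, pts)
        h1 = np.hstack([q1, np.ones((50, 1))])
        h2 = np.hstack([q2, np.ones((50, 1))])
        res = np.abs(np.einsum("ij,jk,ik->i", h2, f, h1))
        assert res.max() < 1e-9

    def test_swapped_views_transpose(self):
        g = make_geom()
        f_swapped = geo.fundamental_matrix(g.swapped())
        f = geo.fundamental_matrix(g)
        # equal up to sign after normalization
        sign = np.sign(f.T.ravel() @ f_swapped.ravel())
        assert np.allclose(f.T, sign * f_swapped, atol=1e-9)

    def test_epipolar_line_metric_distance(self):
        g = make_geom()
        f = geo.fundamental_matrix(g)
        pt = np.array([[5.0, 3.0, 700.0]])
        q1 = geo.project_points(g.p1, pt)[0]
        q2 = geo.project_points(g.p2, pt)[0]
        line = geo.epipolar_line(f, q1)
        assert np.hypot(line[0], line[1]) == pytest.approx(1.0)
        assert abs(geo.point_line_distance(line, q2)[0]) < 1e-9
        # moving delta along the unit normal changes the distance by delta
        normal = line[:2]
        for delta in (0.5, 2.0, -3.0):
            d = geo.point_line_distance(line, q2 + delta * normal)[0]
            assert d == pytest.approx(delta, abs=1e-9)

    def test_geometry_perturbation_moves_line(self):
        intr1 = geo.CameraIntrinsics(sid=1189.0, u0=255.5, v0=255.5)
        intr2 = geo.CameraIntrinsics(sid=1207.0, u0=255.5, v0=255.5)
        pose1 = geo.GantryPose(alpha=-22.9, beta=-27.6, sod=716.44)
        pose2 = geo.GantryPose(alpha=-103.8, beta=13.4, sod=750.0)
        g = geo.build_biplane_geometry(intr1, intr2, pose1, pose2)
        g_bad = geo.build_biplane_geometry(
            intr1, intr2, pose1, geo.GantryPose(alpha=-102.8, beta=13.4, sod=750.0)
        )
        rng = np.random.default_rng(8)
        pts = random_scene_points(rng, 30)
        q1 = geo.project_points(g.p1, pts)
        q2 = geo.project_points(g.p2, pts)
        f_bad = geo.fundamental_matrix(g_bad)
        dists = [
            abs(geo.point_line_distance(geo.epipolar_line(f_bad, a), b)[0])
            for a, b in zip(q1, q2)
        ]
        assert max(dists) > 1.0


class TestBackprojectionError:
    def test_exact_geometry_zero(self):
        g = make_geom()
        rng = np.random.default_rng(2)
        pts = random_scene_points(rng, 40)
        q1 = geo.project_points(g.p1, pts)
        q2 = geo.project_points(g.p2, pts)
        mean, std = geo.backprojection_error(g, q1, q2, pts)
        assert mean < 1e-10 and std < 1e-10

    def test_constant_offset_arithmetic(self):
        g = make_geom()
        rng = np.random.default_rng(2)
        pts = random_scene_points(rng, 40)
        q1 = geo.project_points(g.p1, pts)
        q2 = geo.project_points(g.p2, pts)
        # shift view-1 measurements by 2 px: per-point view-1 distance 2 px,
        # view-2 distance 0; two-view average = 2 * 0.154 / 2 mm
        mean, std = geo.backprojection_error(g, q1 + [2.0, 0.0], q2, pts)
        assert mean == pytest.approx(2 * 0.154 / 2, rel=1e-9)
        assert std < 1e-10

    def test_perturbation_monotonicity(self):
        intr1 = geo.CameraIntrinsics(sid=1189.0, u0=255.5, v0=255.5)
        intr2 = geo.CameraIntrinsics(sid=1207.0, u0=255.5, v0=255.5)
        pose1 = geo.GantryPose(alpha=-22.9, beta=-27.6, sod=716.44)
        rng = np.random.default_rng(4)
        pts = random_scene_points(rng, 40)
        errs = []
        for dalpha in (0.0, 1.0):
            pose2 = geo.GantryPose(alpha=-103.8 + dalpha, beta=13.4, sod=750.0)
            g_true = geo.build_biplane_geometry(intr1, intr2, pose1,
                                                geo.GantryPose(alpha=-103.8, beta=13.4, sod=750.0))
            g_used = geo.build_biplane_geometry(intr1, intr2, pose1, pose2)
            q1 = geo.project_points(g_true.p1, pts)
            q2 = geo.project_points(g_true.p2, pts)
            rec = geo.triangulate_many(g_used.p1, g_used.p2, q1, q2)
            errs.append(geo.backprojection_error(g_used, q1, q2, rec)[0])
        assert errs[1] > errs[0]

    def test_length_mismatch_rejected(self):
        g = make_geom()
        with pytest.raises(geo.GeometryError):
            geo.backprojection_error(g, np.zeros((3, 2)), np.zeros((2, 2)), np.zeros((3, 3)))


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        g = make_geom()
        d = geo.geometry_to_dict(
            g, geo.GantryPose(alpha=-22.9, beta=-27.6, sod=716.44),
            geo.GantryPose(alpha=-103.8, beta=13.4, sod=750.0),
        )
        g2, p1, p2 = geo.geometry_from_dict(d)
        assert np.allclose(g2.p1, g.p1) and np.allclose(g2.p2, g.p2)
        assert p1.alpha == -22.9 and p2.sod == 750.0
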