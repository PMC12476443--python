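"""Pinhole model of the biplane C-arm.

A biplane angiography system is modelled as two pinhole cameras. Each view j
has an intrinsic matrix built from the source-to-image distance SID_j, the
detector pixel spacing (pu, pv), a skew term s and the principal point
(u0, v0)::

    K = [[SID/pu, (SID/pv)*s, u0],
         [0,       SID/pv,    v0],
         [0,       0,          1]]

The gantry pose of a view is the pair of clinical rotation angles
(alpha = LAO/RAO about the patient y axis, beta = CAUD/CRAN about x) plus the
source-to-object distance SOD.  Each view's source sits at its camera origin
with the isocenter on the optical axis at depth SOD, i.e. per-view translation
T_j = (0, 0, SOD_j).  The relative pose between the two views is

    R = Rx(-beta2) Ry(alpha2) (Rx(-beta1) Ry(alpha1))^-1,    T = T2 - R T1.

World coordinates throughout this module are the *first camera's* frame, so
P1 = K1 [I | 0] and P2 = K2 [R | T].  Angles are degrees in all public
interfaces, millimetres for lengths, pixels for image coordinates
(0-based, u = column, v = row, sub-pixel allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "GantryPose",
    "BiplaneGeometry",
    "GeometryError",
    "build_intrinsic_matrix",
    "pose_to_rotation",
    "relative_pose",
    "build_biplane_geometry",
    "pose_transform",
    "project_points",
    "triangulate",
    "triangulate_many",
    "fundamental_matrix",
    "epipolar_line",
    "point_line_distance",
    "backprojection_error",
]


class GeometryError(ValueError):
    """Invalid parameters or a degenerate geometric configuration."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Intrinsic parameters of one C-arm view.

    Parameters
    ----------
    sid : float
        Source-to-image distance in mm.
    pu, pv : float
        Detector pixel spacing in mm/px (default 0.154).
    skew : float
        Dimensionless axis-skew term s (0 for orthogonal detector axes).
    u0, v0 : float
        Principal point in px.
    """

    sid: float
    pu: float = 0.154
    pv: float = 0.154
    skew: float = 0.0
    u0: float = 0.0
    v0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sid > 0 and self.pu > 0 and self.pv > 0):
            raise GeometryError(
                f"sid, pu, pv must be positive (got {self.sid}, {self.pu}, {self.pv})"
            )


@dataclass(frozen=True)
class GantryPose:
    """Gantry record of one view: rotation angles (deg) and SOD (mm)."""

    alpha: float
    beta: float
    sod: float

    def __post_init__(self) -> None:
        if not self.sod > 0:
            raise GeometryError(f"sod must be positive (got {self.sod})")
        if abs(self.alpha) > 180 or abs(self.beta) > 90:
            raise GeometryError(
                f"angles out of range: alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def translation(self) -> np.ndarray:
        """Per-view translation T_j = (0, 0, SOD_j) in the source frame."""
        return np.array([0.0, 0.0, self.sod])


def build_intrinsic_matrix(intr: CameraIntrinsics) -> np.ndarray:
    """3x3 intrinsic matrix K from SID, pixel spacing, skew and principal point."""
    return np.array(
        [
            [intr.sid / intr.pu, (intr.sid / intr.pv) * intr.skew, intr.u0],
            [0.0, intr.sid / intr.pv, intr.v0],
            [0.0, 0.0, 1.0],
        ]
    )


def _rot_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def pose_to_rotation(alpha: float, beta: float) -> np.ndarray:
    """World-to-camera rotation Rx(-beta) @ Ry(alpha) for gantry angles in degrees."""
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise GeometryError("gantry angles must be finite")
    return _rot_x(-beta) @ _rot_y(alpha)


def relative_pose(pose1: GantryPose, pose2: GantryPose) -> tuple[np.ndarray, np.ndarray]:
    """Relative (R, T) of view 2 with respect to view 1.

    R = R2 @ R1^-1 and T = T2 - R @ T1 with the per-view convention
    T_j = (0, 0, SOD_j).
    """
    r1 = pose_to_rotation(pose1.alpha, pose1.beta)
    r2 = pose_to_rotation(pose2.alpha, pose2.beta)
    rot = r2 @ r1.T
    t = pose2.translation - rot @ pose1.translation
    return rot, t


@dataclass(frozen=True)
class BiplaneGeometry:
    """Full projection state of a biplane acquisition.

    World frame = camera-1 frame, so ``p1 = K1 [I|0]`` and ``p2 = K2 [R|T]``.
    Use :func:`build_biplane_geometry` to construct from gantry records.
    """

    intrinsics1: CameraIntrinsics
    intrinsics2: CameraIntrinsics
    rotation: np.ndarray
    translation: np.ndarray
    p1: np.ndarray = field(init=False)
    p2: np.ndarray = field(init=False)
    fundamental: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(rot.T @ rot - np.eye(3)) > 1e-8 or np.linalg.det(rot) < 0:
            raise GeometryError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", t)
        k1 = build_intrinsic_matrix(self.intrinsics1)
        k2 = build_intrinsic_matrix(self.intrinsics2)
        p1 = k1 @ np.hstack([np.eye(3), np.zeros((3, 1))])
        p2 = k2 @ np.hstack([rot, t[:, None]])
        object.__setattr__(self, "p1", p1)
        object.__setattr__(self, "p2", p2)
        object.__setattr__(self, "fundamental", fundamental_matrix_from_projections(p1, p2))

    def swapped(self) -> "BiplaneGeometry":
        """Geometry with the two views exchanged (world frame moves to camera 2)."""
        return BiplaneGeometry(
            intrinsics1=self.intrinsics2,
            intrinsics2=self.intrinsics1,
            rotation=self.rotation.T,
            translation=-self.rotation.T @ self.translation,
        )


def build_biplane_geometry(
    intr1: CameraIntrinsics,
    intr2: CameraIntrinsics,
    pose1: GantryPose,
    pose2: GantryPose,
) -> BiplaneGeometry:
    """Assemble a :class:`BiplaneGeometry` from intrinsics and gantry records."""
    rot, t = relative_pose(pose1, pose2)
    return BiplaneGeometry(intr1, intr2, rot, t)


def pose_transform(pose: GantryPose, points: np.ndarray) -> np.ndarray:
    """Map world (isocenter-frame) points into the camera frame of ``pose``."""
    rot = pose_to_rotation(pose.alpha, pose.beta)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ rot.T + pose.translation


def project_points(p: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Project 3D camera/world points through a 3x4 matrix; returns (n, 2) px.

    Raises
    ------
    GeometryError
        If any point projects to (near) zero depth.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hom = np.hstack([pts, np.ones((len(pts), 1))])
    q = hom @ np.asarray(p, dtype=float).T
    w = q[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise GeometryError("point at zero depth: degenerate projection")
    return q[:, :2] / w[:, None]


def triangulate_many(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Linear (DLT) triangulation of corresponding image points, batched.

    For each pair builds the standard 4x4 homogeneous system from the two
    projection matrices and solves with SVD.
    """
    q1 = np.atleast_2d(np.asarray(q1, dtype=float))
    q2 = np.atleast_2d(np.asarray(q2, dtype=float))
    n = len(q1)
    if len(q2) != n:
        raise GeometryError("correspondence length mismatch")
    a = np.empty((n, 4, 4))
    a[:, 0] = q1[:, 0, None] * p1[2] - p1[0]
    a[:, 1] = q1[:, 1, None] * p1[2] - p1[1]
    a[:, 2] = q2[:, 0, None] * p2[2] - p2[0]
    a[:, 3] = q2[:, 1, None] * p2[2] - p2[1]
    _, s, vt = np.linalg.svd(a)
    x = vt[:, 3, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        pts = x[:, :3] / x[:, 3, None]
    bad = (np.abs(x[:, 3]) < 1e-12) | (s[:, 2] < 1e-9 * s[:, 0])
    if np.any(bad):
        raise GeometryError("ill-posed triangulation (near-parallel rays)")
    return pts


def triangulate(geom: BiplaneGeometry, q1, q2) -> np.ndarray:
    """Triangulate a single correspondence; returns a 3-vector in mm."""
    return triangulate_many(geom.p1, geom.p2, np.asarray(q1), np.asarray(q2))[0]


def fundamental_matrix_from_projections(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Fundamental matrix F = [e2]_x P2 P1^+, Frobenius-normalized.

    ``e2`` is the second-view epipole, the projection of camera 1's center.
    Satisfies q2^T F q1 = 0 for projections of a common 3D point.
    """
    # camera-1 center = null vector of P1
    _, _, vt = np.linalg.svd(p1)
    c1 = vt[3]
    e2 = p2 @ c1
    ex = np.array(
        [[0, -e2[2], e2[1]], [e2[2], 0, -e2[0]], [-e2[1], e2[0], 0]]
    )
    f = ex @ p2 @ np.linalg.pinv(p1)
    norm = np.linalg.norm(f)
    if norm < 1e-15:
        raise GeometryError("degenerate geometry: zero fundamental matrix")
    return f / norm


def fundamental_matrix(geom: BiplaneGeometry) -> np.ndarray:
    """Fundamental matrix of the stored geometry (rank 2, unit Frobenius norm)."""
    return geom.fundamental


def epipolar_line(f: np.ndarray, q1) -> np.ndarray:
    """Epipolar line (a, b, c) in view 2 for point ``q1`` in view 1.

    Normalized so that a^2 + b^2 = 1; then |a u + b v + c| is the
    point-to-line distance in pixels.
    """
    q = np.asarray(q1, dtype=float)
    line = np.asarray(f, dtype=float) @ np.array([q[0], q[1], 1.0])
    norm = np.hypot(line[0], line[1])
    if norm < 1e-15:
        raise GeometryError("degenerate epipolar line (point at the epipole?)")
    return line / norm


def point_line_distance(line: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Signed distance (px) from points (n, 2) to a normalized line (a, b, c)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ line[:2] + line[2]


def backprojection_error(
    geom: BiplaneGeometry,
    centerline1: np.ndarray,
    centerline2: np.ndarray,
    reconstructed: np.ndarray,
) -> tuple[float, float]:
    """Mean and std (mm) of the 2D backprojection error, averaged over views.

    For each reconstructed 3D point the Euclidean distance between the matched
    measured centerline sample and the reprojection is taken in each view,
    converted px -> mm with that view's pixel spacing, and the two views'
    per-point distances are averaged.
    """
    c1 = np.atleast_2d(np.asarray(centerline1, dtype=float))
    c2 = np.atleast_2d(np.asarray(centerline2, dtype=float))
    rec = np.atleast_2d(np.asarray(reconstructed, dtype=float))
    if not (len(c1) == len(c2) == len(rec)):
        raise GeometryError("centerline/reconstruction length mismatch")
    r1 = project_points(geom.p1, rec)
    r2 = project_points(geom.p2, rec)
    sp1 = 0.5 * (geom.intrinsics1.pu + geom.intrinsics1.pv)
    sp2 = 0.5 * (geom.intrinsics2.pu + geom.intrinsics2.pv)
    d1 = np.linalg.norm(r1 - c1, axis=1) * sp1
    d2 = np.linalg.norm(r2 - c2, axis=1) * sp2
    per_point = 0.5 * (d1 + d2)
    return float(per_point.mean()), float(per_point.std())


def geometry_to_dict(
    geom: BiplaneGeometry, pose1: GantryPose | None = None, pose2: GantryPose | None = None
) -> dict:
    """JSON-serializable record of a biplane geometry (matrices row-major)."""

    def view(intr: CameraIntrinsics, pose: GantryPose | None) -> dict:
        d = {
            "sid": intr.sid,
            "pixel_spacing": [intr.pu, intr.pv],
            "skew": intr.skew,
            "u0": intr.u0,
            "v0": intr.v0,
        }
        if pose is not None:
            d.update({"alpha": pose.alpha, "beta": pose.beta, "sod": pose.sod})
        return d

    return {
        "view1": view(geom.intrinsics1, pose1),
        "view2": view(geom.intrinsics2, pose2),
        "rotation": geom.rotation.tolist(),
        "translation": geom.translation.tolist(),
        "p1": geom.p1.tolist(),
        "p2": geom.p2.tolist(),
        "fundamental": geom.fundamental.tolist(),
    }


def geometry_from_dict(d: dict) -> tuple[BiplaneGeometry, GantryPose | None, GantryPose | None]:
    """Rebuild a geometry (and gantry poses, when present) from its JSON record."""
    def intr(v: dict) -> CameraIntrinsics:
        pu, pv = v.get("pixel_spacing", [0.154, 0.154])
        return CameraIntrinsics(
            sid=v["sid"], pu=pu, pv=pv, skew=v.get("skew", 0.0),
            u0=v.get("u0", 0.0), v0=v.get("v0", 0.0),
        )

    def pose(v: dict) -> GantryPose | None:
        if "alpha" in v and "sod" in v:
            return GantryPose(alpha=v["alpha"], beta=v["beta"], sod=v["sod"])
        return None

    i1, i2 = intr(d["view1"]), intr(d["view2"])
    po1, po2 = pose(d["view1"]), pose(d["view2"])
    if "rotation" in d:
        geom = BiplaneGeometry(i1, i2, np.array(d["rotation"]), np.array(d["translation"]))
    elif po1 is not None and po2 is not None:
        geom = build_biplane_geometry(i1, i2, po1, po2)
    else:
        raise GeometryError("geometry record needs either rotation/translation or gantry poses")
    return geom, po1, po2
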