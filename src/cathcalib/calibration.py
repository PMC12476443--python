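"""Biplane self-calibration from segmented catheter centerlines.

The gantry-recorded geometry initializes 14 parameters — per view the
source-to-image distance SID_j, skew s_j and principal point (u0_j, v0_j),
plus the relative rotation (3 angle offsets) and translation T (3).  One
hundred evenly spaced samples on the view-1 centerline are matched to the
view-2 centerline (200 samples) through epipolar lines: a candidate match
must lie within 2.25 px of the epipolar line, and when several candidates
exist a jump criterion keeps only matches whose Euclidean step from the
previous match agrees with the step along the centerline to within 1 px.

The cost is the sum over correspondences of squared distances between the
measured points and the reprojections of their triangulated 3D points, in
both views, plus squared differences of consecutive-point unit direction
vectors (measured vs reprojected, both views).  It is minimized by bounded
nonlinear least squares in two stages: first on the exact landmark (tip /
marker) pairs alone, then alternating correspondence selection and
refinement over the whole centerline.  The known physical landmark
separation fixes the reconstruction scale afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from cathcalib.geometry import (
    BiplaneGeometry,
    CameraIntrinsics,
    GantryPose,
    GeometryError,
    backprojection_error,
    epipolar_line,
    project_points,
    relative_pose,
    triangulate_many,
)
from cathcalib.postprocess import CatheterCenterline

__all__ = [
    "CalibrationParams",
    "CorrespondenceSet",
    "CalibrationResult",
    "ParameterBounds",
    "sample_centerline",
    "find_correspondences",
    "cost_function",
    "initialize_from_gantry",
    "optimize_tips",
    "optimize_full",
    "reconstruct_3d",
    "EPIPOLAR_LIMIT",
    "JUMP_LIMIT",
]

EPIPOLAR_LIMIT = 2.25  # px, max distance of an accepted match to the epipolar line
JUMP_LIMIT = 1.0  # px, max |euclidean step - arclength step| between matches
N_SAMPLES_VIEW1 = 100
N_SAMPLES_VIEW2 = 200
MIN_CORRESPONDENCES = 8
MATCH_TOLERANCE_PX = 0.5  # mean backprojection error declaring "closely matched"
LENGTH_WEIGHT = 1.0  # weight (per mm) of the landmark-length term in the cost
LENGTH_TOLERANCE = 0.01  # relative landmark-length mismatch allowed at convergence


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds around the initial parameters (offsets).

    Sized to bracket the calibration shifts a functioning biplane system
    actually exhibits — a few degrees in the gantry angles and a few mm in
    SID and translation — with margin.  Deviations beyond these bounds are
    outside the operating envelope of online self-calibration (a grossly
    mis-recorded geometry cannot be recovered from a catheter alone)."""

    sid_mm: float = 10.0
    skew: float = 0.01
    principal_px: float = 50.0
    angle_deg: float = 5.0
    translation_mm: float = 10.0


@dataclass
class CalibrationParams:
    """Optimizable geometry state: intrinsics per view + relative pose.

    The rotation is parameterized as three Euler-style angle offsets (deg)
    applied to a stored reference rotation ``r0`` so that box bounds on the
    offsets stay meaningful across iterations.
    """

    intr1: CameraIntrinsics
    intr2: CameraIntrinsics
    r0: np.ndarray
    rot_offsets_deg: np.ndarray
    translation: np.ndarray

    def copy(self) -> "CalibrationParams":
        return CalibrationParams(
            self.intr1, self.intr2, self.r0.copy(),
            np.array(self.rot_offsets_deg, float), np.array(self.translation, float),
        )

    @property
    def rotation(self) -> np.ndarray:
        rx, ry, rz = self.rot_offsets_deg
        return _euler(rx, ry, rz) @ self.r0

    def geometry(self) -> BiplaneGeometry:
        return BiplaneGeometry(self.intr1, self.intr2, self.rotation, self.translation)

    # --- flat-vector encoding used by the optimizer -----------------------
    def to_vector(self) -> np.ndarray:
        i1, i2 = self.intr1, self.intr2
        return np.array(
            [i1.sid, i2.sid, i1.skew, i2.skew, i1.u0, i1.v0, i2.u0, i2.v0]
            + list(self.rot_offsets_deg)
            + list(self.translation)
        )

    def with_vector(self, v: np.ndarray) -> "CalibrationParams":
        i1, i2 = self.intr1, self.intr2
        return CalibrationParams(
            intr1=CameraIntrinsics(sid=v[0], pu=i1.pu, pv=i1.pv, skew=v[2], u0=v[4], v0=v[5]),
            intr2=CameraIntrinsics(sid=v[1], pu=i2.pu, pv=i2.pv, skew=v[3], u0=v[6], v0=v[7]),
            r0=self.r0,
            rot_offsets_deg=np.array(v[8:11], float),
            translation=np.array(v[11:14], float),
        )

    def bounds_around(self, b: ParameterBounds) -> tuple[np.ndarray, np.ndarray]:
        v = self.to_vector()
        d = np.array(
            [b.sid_mm, b.sid_mm, b.skew, b.skew]
            + [b.principal_px] * 4
            + [b.angle_deg] * 3
            + [b.translation_mm] * 3
        )
        return v - d, v + d


def _euler(rx: float, ry: float, rz: float) -> np.ndarray:
    """Small-offset rotation Rz(rz) @ Ry(ry) @ Rx(rx), degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


@dataclass
class CorrespondenceSet:
    """Accepted matches between view-1 samples and view-2 sub-pixel points."""

    indices1: np.ndarray  # indices into the view-1 sample list (strictly increasing)
    points1: np.ndarray  # (n, 2) view-1 samples
    points2: np.ndarray  # (n, 2) matched view-2 points
    arclengths2: np.ndarray  # arclength (px) of each match along the view-2 centerline
    epipolar_distances: np.ndarray
    exact: np.ndarray  # bool: landmark pair (exact) vs epipolar-derived

    def __len__(self) -> int:
        return len(self.indices1)


@dataclass
class CalibrationResult:
    """Outcome of the full two-stage refinement."""

    params: CalibrationParams
    correspondences: CorrespondenceSet | None
    reconstructed: np.ndarray | None
    cost_trace: list[float]
    error_before_mm: tuple[float, float]
    error_after_mm: tuple[float, float]
    error_after_px: float
    status: str  # converged | max-iter | not-terminated
    n_outer_iterations: int = 0
    message: str = ""


def sample_centerline(centerline: CatheterCenterline | np.ndarray, n: int) -> np.ndarray:
    """``n`` points at equal arclength spacing along a polyline, endpoints included."""
    pts = centerline.points if isinstance(centerline, CatheterCenterline) else np.asarray(centerline, float)
    if n < 2:
        raise ValueError("n must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate centerline with zero arclength")
    targets = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, pts[:, 0])
    out[:, 1] = np.interp(targets, s, pts[:, 1])
    return out


def _polyline_arclength(pts: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])


def _line_polyline_candidates(
    line: np.ndarray, poly: np.ndarray, s: np.ndarray, limit: float
) -> list[tuple[np.ndarray, float, float]]:
    """Candidate matches on a polyline for one epipolar line.

    Returns (point, arclength, epipolar_distance) triples: all sub-pixel
    segment intersections (distance 0) plus, when none intersect, the nearest
    vertex within ``limit`` px of the line.
    """
    d = poly @ line[:2] + line[2]
    out = []
    sign_change = np.nonzero(d[:-1] * d[1:] < 0)[0]
    for i in sign_change:
        t = d[i] / (d[i] - d[i + 1])
        p = poly[i] + t * (poly[i + 1] - poly[i])
        out.append((p, s[i] + t * (s[i + 1] - s[i]), 0.0))
    for i in np.nonzero(d == 0)[0]:
        out.append((poly[i], s[i], 0.0))
    if not out:
        j = int(np.argmin(np.abs(d)))
        if abs(d[j]) <= limit:
            out.append((poly[j], s[j], abs(d[j])))
    return out


def find_correspondences(
    geom: BiplaneGeometry,
    samples1: np.ndarray,
    centerline2: np.ndarray,
    use_jump_criterion: bool = True,
    epipolar_limit: float = EPIPOLAR_LIMIT,
    jump_limit: float = JUMP_LIMIT,
) -> CorrespondenceSet:
    """Match view-1 samples to the view-2 centerline through epipolar lines.

    ``centerline2`` is the (typically 200-point) evenly resampled view-2
    polyline.  Samples whose epipolar line misses the centerline by more than
    ``epipolar_limit`` px are dropped; with several candidates the jump
    criterion (|Euclidean step - arclength step| < ``jump_limit`` relative to
    the previous accepted match) filters implausible matches, ties broken by
    epipolar distance.

    Raises
    ------
    GeometryError
        If fewer than 8 samples can be matched.
    """
    poly = np.asarray(centerline2, dtype=float)
    s2 = _polyline_arclength(poly)
    f = geom.fundamental
    idx, p1s, p2s, arcs, dists = [], [], [], [], []
    prev_p: np.ndarray | None = None
    prev_s: float | None = None
    for i, q1 in enumerate(np.atleast_2d(samples1)):
        try:
            line = epipolar_line(f, q1)
        except GeometryError:
            continue
        cands = _line_polyline_candidates(line, poly, s2, epipolar_limit)
        if not cands:
            continue
        if use_jump_criterion and prev_p is not None:
            # a plausible continuation steps *forward* along the view-2 curve
            # by about the same amount it moves in the image; backward moves
            # and teleports across a loop both fail the 1-px agreement test
            cands = [
                (p, s, d)
                for p, s, d in cands
                if s >= prev_s - jump_limit
                and abs(np.linalg.norm(p - prev_p) - (s - prev_s)) < jump_limit
            ]
            if not cands:
                continue  # every candidate implies a sudden jump: drop sample
        if prev_p is not None:
            # among surviving candidates prefer small epipolar distance, then
            # the smallest forward arclength step
            cands.sort(key=lambda c: (c[2], c[1] < prev_s, abs(c[1] - prev_s)))
        else:
            cands.sort(key=lambda c: c[2])
        p, s, d = cands[0]
        idx.append(i)
        p1s.append(q1)
        p2s.append(p)
        arcs.append(s)
        dists.append(d)
        prev_p, prev_s = p, s
    if len(idx) < MIN_CORRESPONDENCES:
        raise GeometryError(
            f"insufficient correspondences: {len(idx)} < {MIN_CORRESPONDENCES}"
        )
    return CorrespondenceSet(
        indices1=np.array(idx),
        points1=np.array(p1s),
        points2=np.array(p2s),
        arclengths2=np.array(arcs),
        epipolar_distances=np.array(dists),
        exact=np.zeros(len(idx), dtype=bool),
    )


def _directions(pts: np.ndarray) -> np.ndarray:
    d = np.diff(pts, axis=0)
    n = np.linalg.norm(d, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return d / n


def _residuals(
    params: CalibrationParams,
    points1: np.ndarray,
    points2: np.ndarray,
    with_directions: bool = True,
    landmarks: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> np.ndarray:
    """Residual vector of the calibration cost for fixed correspondences.

    ``landmarks`` = (tips1, tips2, physical_length_mm) adds the metric-scale
    term: the reconstructed landmark separation minus the known physical
    length, weighted by LENGTH_WEIGHT.
    """
    geom = params.geometry()
    try:
        q3d = triangulate_many(geom.p1, geom.p2, points1, points2)
        r1 = project_points(geom.p1, q3d)
        r2 = project_points(geom.p2, q3d)
    except GeometryError:
        warnings.warn("triangulation failed inside cost; returning penalty", stacklevel=2)
        n = len(points1) * 4 + (len(points1) - 1) * 4 * with_directions
        return np.full(max(n, 1), 1e6)
    res = [(points1 - r1).ravel(), (points2 - r2).ravel()]
    if with_directions and len(points1) > 1:
        res.append((_directions(points1) - _directions(r1)).ravel())
        res.append((_directions(points2) - _directions(r2)).ravel())
    if landmarks is not None:
        res.append(LENGTH_WEIGHT * np.atleast_1d(_length_residual(geom, *landmarks)))
    return np.concatenate(res)


def _length_residual(geom: BiplaneGeometry, tips1, tips2, length_mm: float) -> float:
    try:
        rec = triangulate_many(geom.p1, geom.p2, tips1, tips2)
    except GeometryError:
        return 1e6
    return float(np.linalg.norm(rec[0] - rec[1]) - length_mm)


def cost_function(
    params: CalibrationParams, correspondences: CorrespondenceSet
) -> float:
    """Scalar value of the calibration cost (sum of squared residuals)."""
    if len(correspondences) < MIN_CORRESPONDENCES:
        raise ValueError("need at least 8 correspondences")
    r = _residuals(params, correspondences.points1, correspondences.points2)
    return float(r @ r)


def initialize_from_gantry(
    intr1: CameraIntrinsics,
    intr2: CameraIntrinsics,
    pose1: GantryPose,
    pose2: GantryPose,
    image_shape: tuple[int, int] | None = None,
) -> CalibrationParams:
    """Initial parameters: skew 0, principal point at the image center,
    SID from the record, (R, T) from the recorded gantry poses."""
    if image_shape is not None:
        v0, u0 = (image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0
        intr1 = CameraIntrinsics(sid=intr1.sid, pu=intr1.pu, pv=intr1.pv, skew=0.0, u0=u0, v0=v0)
        intr2 = CameraIntrinsics(sid=intr2.sid, pu=intr2.pu, pv=intr2.pv, skew=0.0, u0=u0, v0=v0)
    rot, t = relative_pose(pose1, pose2)
    if np.linalg.norm(t) < 1e-9:
        warnings.warn("degenerate baseline: identical poses", stacklevel=2)
    return CalibrationParams(
        intr1=intr1, intr2=intr2, r0=rot,
        rot_offsets_deg=np.zeros(3), translation=t,
    )


_X_SCALE = np.array([2.0, 2.0, 1e-4, 1e-4, 0.5, 0.5, 0.5, 0.5, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
"""Characteristic parameter scales for the trust-region solver.

Set to the magnitude each parameter is expected to deviate from its gantry
initialization: SID and T a few mm, gantry angles about a degree, the
principal point a fraction of a pixel from the image center, skew near zero.
The scaling matters beyond conditioning: reprojection residuals are nearly
invariant to a rotation compensated by a principal-point shift (the classic
tilt/shift gauge ambiguity), and these scales make the solver spend that
freedom on the physically plausible parameters."""


PRIOR_WEIGHT = 0.01
"""Weight of the gantry-record prior in the least-squares residual.

The reprojection cost is gauge-degenerate: epipolar-derived matches are
consistent with the geometry that selected them, and a rotation can trade
off against a principal-point shift, so whole directions of parameter space
leave the data residual flat.  A weak Tikhonov term (v - v_init)/x_scale
pulls those flat directions to the recorded gantry values — px-scale data
residuals dominate it everywhere the data constrain the geometry."""


def _lsq(fun, v0, lo, hi, max_nfev: int | None = None, prior_weight: float = PRIOR_WEIGHT,
         anchor: np.ndarray | None = None):
    v_init = np.array(v0 if anchor is None else anchor, dtype=float)

    def fun_with_prior(v):
        return np.concatenate(
            [fun(v), prior_weight * (v - v_init) / _X_SCALE]
        )

    return least_squares(
        fun_with_prior, v0, bounds=(lo, hi), method="trf", x_scale=_X_SCALE,
        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev,
    )


def optimize_tips(
    params0: CalibrationParams,
    tips1: np.ndarray,
    tips2: np.ndarray,
    bounds: ParameterBounds = ParameterBounds(),
    physical_length_mm: float | None = None,
) -> CalibrationParams:
    """Stage 1: refine parameters on the exact landmark pairs only.

    ``tips1``/``tips2`` are the (>= 2) landmark image points designated in
    each view (catheter tip and radio-opaque markers), treated as exact
    correspondences; the distance term plus, when the physical landmark
    separation is known, the metric-length term apply.
    """
    t1 = np.atleast_2d(np.asarray(tips1, float))
    t2 = np.atleast_2d(np.asarray(tips2, float))
    if len(t1) < 2 or len(t1) != len(t2):
        raise ValueError("need >= 2 landmark pairs, equal in both views")
    lo, hi = params0.bounds_around(bounds)
    v0 = params0.to_vector()
    lmk = (t1, t2, physical_length_mm) if physical_length_mm else None

    def fun(v):
        return _residuals(
            params0.with_vector(v), t1, t2, with_directions=False, landmarks=lmk
        )

    try:
        sol = _lsq(fun, v0, lo, hi)
    except Exception as exc:  # pragma: no cover
        warnings.warn(f"tip-stage optimization failed: {exc}", stacklevel=2)
        return params0.copy()
    return params0.with_vector(sol.x)


def optimize_full(
    params1: CalibrationParams,
    centerline1: CatheterCenterline,
    centerline2: CatheterCenterline,
    bounds: ParameterBounds = ParameterBounds(),
    n_samples1: int = N_SAMPLES_VIEW1,
    n_samples2: int = N_SAMPLES_VIEW2,
    use_jump_criterion: bool = True,
    max_outer: int = 30,
    cost_rtol: float = 1e-6,
    step_tol: float = 1e-8,
    lm_max_nfev: int = 1500,
    match_tolerance_px: float = MATCH_TOLERANCE_PX,
    params_before: CalibrationParams | None = None,
) -> CalibrationResult:
    """Stage 2: alternate correspondence selection and bounded least squares.

    Each outer iteration re-selects correspondences under the current
    geometry, then refines all 14 parameters.  The loop stops when the
    relative cost change falls below ``cost_rtol``, the parameter step below
    ``step_tol``, or after ``max_outer`` iterations.  Afterwards the
    translation is rescaled so the reconstructed landmark separation equals
    the stored physical length.

    Status is ``converged`` only when the final mean backprojection error is
    below ``match_tolerance_px`` — the backprojection "closely matches" the
    measured centerline; otherwise ``max-iter`` (loop exhausted) or
    ``not-terminated`` (solver budget exhausted or correspondences lost).
    """
    samples1 = sample_centerline(centerline1, n_samples1)
    poly2 = sample_centerline(centerline2, n_samples2)
    # the landmark pairs are the only correspondences known independently of
    # the geometry; they anchor the cost (epipolar-derived matches are, by
    # construction, consistent with whichever geometry selected them)
    tips1 = _landmark_points(centerline1)
    tips2 = _landmark_points(centerline2)
    physical_length = centerline1.physical_length_mm or centerline2.physical_length_mm
    # the trust region brackets the *recorded* gantry geometry, so stage-1
    # drift cannot relocate the feasible box
    lo, hi = (params_before or params1).bounds_around(bounds)
    params = params1.copy()
    v = np.clip(params.to_vector(), lo, hi)
    params = params1.with_vector(v)
    v_anchor = v.copy()  # the prior anchors every outer iteration to stage-1
    cost_trace: list[float] = []
    status = "max-iter"
    message = ""
    corr: CorrespondenceSet | None = None
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        try:
            corr = find_correspondences(
                params.geometry(), samples1, poly2,
                use_jump_criterion=use_jump_criterion,
            )
        except GeometryError as exc:
            status = "not-terminated"
            message = str(exc)
            break
        corr = _with_exact_pairs(corr, tips1, tips2)

        p1c, p2c = corr.points1, corr.points2

        lmk = (tips1, tips2, physical_length) if physical_length else None

        def fun(vec, _p1=p1c, _p2=p2c, _lmk=lmk):
            return _residuals(params1.with_vector(vec), _p1, _p2, landmarks=_lmk)

        sol = _lsq(fun, v, lo, hi, max_nfev=lm_max_nfev, anchor=v_anchor)
        r_data = fun(sol.x)
        cost = float(r_data @ r_data)  # data term only (prior excluded)
        step = np.linalg.norm(sol.x - v)
        v = sol.x
        params = params1.with_vector(v)
        cost_trace.append(float(cost))
        # enforce the known catheter length: rescale T toward the physical
        # landmark separation, clipped into the trust bounds; the next inner
        # solve re-polishes consistency around the corrected scale
        if physical_length:
            params = _enforce_scale(params, tips1, tips2, physical_length, lo, hi)
            v = np.clip(params.to_vector(), lo, hi)
            params = params1.with_vector(v)
        # early exit only when the backprojection matches tightly and the
        # metric scale is consistent; borderline runs use the whole outer
        # budget (the alternation converges slowly and non-monotonically)
        _, err_px_now = _final_error(params, corr)
        length_ok_now = _length_mismatch_ok(params, tips1, tips2, physical_length)
        if err_px_now < 0.01 * match_tolerance_px and length_ok_now:
            status = "matched"
            break
        if sol.status == 0:
            status = "not-terminated"
            message = "inner solver exhausted its evaluation budget"
            break
        if len(cost_trace) > 1:
            prev = cost_trace[-2]
            if prev > 0 and abs(prev - cost) / prev < cost_rtol:
                status = "stalled"
                break
        if step < step_tol:
            status = "stalled"
            break

    # landmark-scale step + final error audit; "before" = the uncalibrated
    # (gantry-recorded) parameters when the caller provides them
    error_before = _audit_error(params_before or params1, corr, samples1, poly2)
    # metric-scale audit before the final (unbounded, reporting-only) rescale
    length_ok = _length_mismatch_ok(params, tips1, tips2, physical_length)
    params, rec = _apply_landmark_scale(params, centerline1, centerline2)
    error_after, err_px = _final_error(params, corr)
    if status in ("matched", "stalled", "max-iter"):
        if err_px < match_tolerance_px and length_ok:
            status = "converged"
        else:
            status = "max-iter"
            if not length_ok:
                message = message or "landmark length not reachable within parameter bounds"
    return CalibrationResult(
        params=params,
        correspondences=corr,
        reconstructed=rec,
        cost_trace=cost_trace,
        error_before_mm=error_before,
        error_after_mm=error_after,
        error_after_px=err_px,
        status=status,
        n_outer_iterations=n_outer,
        message=message,
    )


def _with_exact_pairs(
    corr: CorrespondenceSet, tips1: np.ndarray, tips2: np.ndarray
) -> CorrespondenceSet:
    """Prepend the exact landmark pairs to an epipolar-derived set."""
    n = len(tips1)
    return CorrespondenceSet(
        indices1=np.concatenate([np.full(n, -1), corr.indices1]),
        points1=np.vstack([tips1, corr.points1]),
        points2=np.vstack([tips2, corr.points2]),
        arclengths2=np.concatenate([np.full(n, np.nan), corr.arclengths2]),
        epipolar_distances=np.concatenate([np.zeros(n), corr.epipolar_distances]),
        exact=np.concatenate([np.ones(n, bool), corr.exact]),
    )


def _landmark_distance(params: CalibrationParams, tips1, tips2) -> float | None:
    geom = params.geometry()
    try:
        rec = triangulate_many(geom.p1, geom.p2, tips1, tips2)
    except GeometryError:
        return None
    return float(np.linalg.norm(rec[0] - rec[1]))


def _length_mismatch_ok(
    params: CalibrationParams, tips1, tips2, physical_length: float | None
) -> bool:
    if not physical_length:
        return True
    d = _landmark_distance(params, tips1, tips2)
    if d is None:
        return False
    return abs(d - physical_length) / physical_length < LENGTH_TOLERANCE


def _enforce_scale(
    params: CalibrationParams,
    tips1: np.ndarray,
    tips2: np.ndarray,
    physical_length: float,
    lo: np.ndarray,
    hi: np.ndarray,
) -> CalibrationParams:
    """Rescale T so the reconstructed landmark separation approaches the
    known physical length, clipped into the trust bounds."""
    d = _landmark_distance(params, tips1, tips2)
    if d is None or d < 1e-9:
        return params
    s = physical_length / d
    # clip the *scalar* scale so s*T stays inside the box (a per-component
    # clip would change T's direction and wreck the epipolar geometry)
    t = params.translation
    s_lo, s_hi = -np.inf, np.inf
    for ti, li, hi_i in zip(t, lo[11:14], hi[11:14]):
        if abs(ti) < 1e-12:
            continue
        a, b = sorted((li / ti, hi_i / ti))
        s_lo, s_hi = max(s_lo, a), min(s_hi, b)
    if s_lo > s_hi:  # empty feasible range: leave T unchanged
        return params
    s = float(np.clip(s, s_lo, s_hi))
    out = params.copy()
    out.translation = t * s
    return out


def _audit_error(
    params0: CalibrationParams, corr: CorrespondenceSet | None,
    samples1: np.ndarray, poly2: np.ndarray,
) -> tuple[float, float]:
    """Backprojection error (mm) of the *initial* parameters on the final
    correspondence pairs (falls back to a fresh match under params0)."""
    if corr is None:
        try:
            corr = find_correspondences(params0.geometry(), samples1, poly2)
        except GeometryError:
            return (float("nan"), float("nan"))
    geom = params0.geometry()
    try:
        rec = triangulate_many(geom.p1, geom.p2, corr.points1, corr.points2)
        return backprojection_error(geom, corr.points1, corr.points2, rec)
    except GeometryError:
        return (float("nan"), float("nan"))


def _final_error(
    params: CalibrationParams, corr: CorrespondenceSet | None
) -> tuple[tuple[float, float], float]:
    if corr is None:
        return (float("nan"), float("nan")), float("inf")
    geom = params.geometry()
    try:
        rec = triangulate_many(geom.p1, geom.p2, corr.points1, corr.points2)
    except GeometryError:
        return (float("nan"), float("nan")), float("inf")
    err_mm = backprojection_error(geom, corr.points1, corr.points2, rec)
    spacing = 0.25 * (geom.intrinsics1.pu + geom.intrinsics1.pv
                      + geom.intrinsics2.pu + geom.intrinsics2.pv)
    return err_mm, err_mm[0] / spacing


def _landmark_points(c: CatheterCenterline) -> np.ndarray:
    if c.landmark_indices is None:
        return np.array([c.points[0], c.points[-1]])
    return c.points[list(c.landmark_indices)]


def _apply_landmark_scale(
    params: CalibrationParams,
    centerline1: CatheterCenterline,
    centerline2: CatheterCenterline,
) -> tuple[CalibrationParams, np.ndarray | None]:
    """Rescale T so the reconstructed landmark separation equals the known
    physical length (scaling T scales the whole metric reconstruction while
    leaving every reprojection unchanged)."""
    length = centerline1.physical_length_mm or centerline2.physical_length_mm
    if length is None:
        return params, None
    lm1 = _landmark_points(centerline1)
    lm2 = _landmark_points(centerline2)
    geom = params.geometry()
    try:
        rec = triangulate_many(geom.p1, geom.p2, lm1, lm2)
    except GeometryError:
        warnings.warn("landmark triangulation failed; scale not applied", stacklevel=2)
        return params, None
    d = float(np.linalg.norm(rec[0] - rec[1]))
    if d < 1e-9:
        warnings.warn("degenerate landmark separation; scale not applied", stacklevel=2)
        return params, None
    scale = length / d
    out = params.copy()
    out.translation = params.translation * scale
    return out, rec * scale


def reconstruct_3d(result: CalibrationResult) -> tuple[np.ndarray, float | None]:
    """Triangulate the accepted correspondences with the final parameters.

    Returns the 3D centerline (mm, camera-1 frame) and, when landmark pairs
    are available in the result, the reconstructed inter-landmark distance.
    """
    if result.correspondences is None:
        raise ValueError("result has no correspondences to reconstruct")
    geom = result.params.geometry()
    corr = result.correspondences
    pts = triangulate_many(geom.p1, geom.p2, corr.points1, corr.points2)
    dist = None
    if result.reconstructed is not None and len(result.reconstructed) == 2:
        dist = float(np.linalg.norm(result.reconstructed[0] - result.reconstructed[1]))
    return pts, dist
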