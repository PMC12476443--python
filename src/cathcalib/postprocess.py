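"""Vessel-map post-processing and centerline extraction.

The contrast-enhanced sequence is digitally subtracted (middle frames minus
the first, pre-contrast frame); each difference image's 64-bin histogram is
fitted with a Gaussian a*exp(-((x-b)/c)^2) and frames whose peak center b
falls below 0.65 are discarded (little contrast present).  Eligible frames
are binarized by 1D 2-means on intensity (the darker cluster is vessel),
summed into a vessel map, smoothed, hole-filled, dilated and reduced to the
largest connected component.  Candidate detections outside the map are false
positives and removed.  The surviving catheter mask is skeletonized, spurs
are pruned, disconnected skeleton pieces are bridged with Akima cubic Hermite
interpolation, and the centerline is clipped to two user landmarks whose
physical separation (e.g. the 30 mm inter-marker length) anchors the
reconstruction scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import Akima1DInterpolator
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from skimage.measure import label
from skimage.morphology import dilation as binary_dilation, disk, remove_small_holes, skeletonize

__all__ = [
    "DSAFrame",
    "VesselMask",
    "CatheterCenterline",
    "dsa_subtract",
    "fit_histogram_gaussian",
    "kmeans_vessel_segment",
    "build_vessel_map",
    "remove_false_positives",
    "extract_centerline",
    "fill_gaps",
    "clip_to_landmarks",
    "B_CUTOFF",
]

B_CUTOFF = 0.65  # Gaussian-peak-center threshold for contrast-frame eligibility
HIST_BINS = 64


@dataclass
class DSAFrame:
    """One digital-subtraction frame, rescaled to [0, 1]."""

    image: np.ndarray
    frame_index: int
    b: float | None = None  # histogram Gaussian peak center
    fit_residual: float | None = None
    discarded: bool = False


@dataclass
class VesselMask:
    """Binary vessel map plus a provenance trace of how it was built."""

    mask: np.ndarray
    frames_used: list[int] = field(default_factory=list)
    trace: list[str] = field(default_factory=list)


@dataclass
class CatheterCenterline:
    """Ordered sub-pixel centerline with arclength bookkeeping.

    ``points`` is (n, 2) in (u, v) = (col, row) pixels; ``arclength_px`` is
    the cumulative chord length.  Landmarks are indices into ``points``; the
    physical landmark separation (mm) anchors scale during calibration.
    """

    points: np.ndarray
    pixel_spacing: float = 0.154
    landmark_indices: tuple[int, int] | None = None
    physical_length_mm: float | None = None

    @property
    def arclength_px(self) -> np.ndarray:
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def arclength_mm(self) -> np.ndarray:
        return self.arclength_px * self.pixel_spacing

    @property
    def length_px(self) -> float:
        return float(self.arclength_px[-1])

    def __len__(self) -> int:
        return len(self.points)


def dsa_subtract(sequence: np.ndarray) -> list[DSAFrame]:
    """Subtract the first (mask) frame from every later frame; rescale to [0, 1]."""
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 3 or seq.shape[0] < 3:
        raise ValueError("sequence must be (n>=3, rows, cols)")
    ref = seq[0]
    out = []
    for k in range(1, seq.shape[0]):
        diff = seq[k] - ref
        rng = diff.max() - diff.min()
        img = (diff - diff.min()) / rng if rng > 1e-12 else np.zeros_like(diff)
        out.append(DSAFrame(image=img, frame_index=k))
    return out


def _gaussian(x, a, b, c):
    return a * np.exp(-(((x - b) / c) ** 2))


def fit_histogram_gaussian(dsa: DSAFrame, bins: int = HIST_BINS) -> float:
    """Fit a Gaussian to the normalized-intensity histogram; returns center b.

    On fit failure the frame is marked discarded (with a warning) and NaN is
    returned.
    """
    hist, edges = np.histogram(dsa.image.ravel(), bins=bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = centers[int(np.argmax(hist))]
    try:
        popt, _ = curve_fit(
            _gaussian,
            centers,
            hist.astype(float),
            p0=(float(hist.max()), float(mode), 0.1),
            maxfev=5000,
        )
    except RuntimeError:
        warnings.warn(f"histogram fit failed on frame {dsa.frame_index}", stacklevel=2)
        dsa.discarded = True
        dsa.b = float("nan")
        return dsa.b
    dsa.b = float(popt[1])
    dsa.fit_residual = float(
        np.sqrt(np.mean((hist - _gaussian(centers, *popt)) ** 2))
    )
    dsa.discarded = not (dsa.b >= B_CUTOFF)
    return dsa.b


def kmeans_vessel_segment(dsa: DSAFrame) -> np.ndarray:
    """1D 2-means on intensity; the darker cluster (contrast) is vessel.

    Deterministic: centers initialized at the 10th/90th intensity percentiles
    and iterated to convergence (Lloyd's algorithm on the 1D sample).
    """
    vals = dsa.image.ravel()
    c = np.percentile(vals, [10.0, 90.0]).astype(float)
    if c[1] - c[0] < 1e-12:
        return np.zeros(dsa.image.shape, dtype=bool)
    for _ in range(100):
        thr = 0.5 * (c[0] + c[1])
        low = vals <= thr
        new = np.array([
            vals[low].mean() if low.any() else c[0],
            vals[~low].mean() if (~low).any() else c[1],
        ])
        if np.allclose(new, c, atol=1e-12):
            break
        c = new
    thr = 0.5 * (c[0] + c[1])
    return (dsa.image <= thr).reshape(dsa.image.shape)


def build_vessel_map(
    binary_frames: list[np.ndarray],
    vote_threshold: int = 1,
    frames_used: list[int] | None = None,
) -> VesselMask:
    """Sum eligible binarized frames into a single refined vessel mask.

    Pipeline: pixel-wise vote >= ``vote_threshold`` -> Gaussian smoothing
    (sigma 1) re-binarized at 0.5 -> hole filling -> dilation (disk r=3) ->
    largest 8-connected component.
    """
    if not binary_frames:
        raise ValueError("need at least one eligible frame")
    votes = np.sum([f.astype(int) for f in binary_frames], axis=0)
    mask = votes >= vote_threshold
    trace = [f"votes>={vote_threshold}: {int(mask.sum())} px"]
    if not mask.any():
        warnings.warn("empty vessel-map union", stacklevel=2)
        return VesselMask(mask=mask, frames_used=frames_used or [], trace=trace)
    mask = gaussian_filter(mask.astype(float), 1.0) > 0.5
    # fill interior gaps of the tube but not large enclosed backgrounds
    mask = remove_small_holes(mask, max_size=500)
    mask = binary_dilation(mask, disk(3))
    lab = label(mask, connectivity=2)
    if lab.max() > 0:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == int(np.argmax(sizes))
    trace.append(f"final: {int(mask.sum())} px")
    return VesselMask(mask=mask, frames_used=frames_used or [], trace=trace)


def remove_false_positives(candidate: np.ndarray, vessel: VesselMask) -> np.ndarray:
    """Keep only candidate pixels inside the vessel map (set intersection)."""
    cand = np.asarray(candidate, dtype=bool)
    if cand.shape != vessel.mask.shape:
        raise ValueError("shape mismatch between candidate mask and vessel map")
    return cand & vessel.mask


# ---------------------------------------------------------------------------
# skeleton machinery

_NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbors(skel: np.ndarray, r: int, c: int):
    nr, nc = skel.shape
    for dr, dc in _NB8:
        rr, cc = r + dr, c + dc
        if 0 <= rr < nr and 0 <= cc < nc and skel[rr, cc]:
            yield rr, cc


def _degree_map(skel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import convolve

    k = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    return convolve(skel.astype(int), k, mode="constant") * skel


def _prune_spurs(skel: np.ndarray, max_len: int = 10) -> np.ndarray:
    """Iteratively remove branch tips shorter than ``max_len`` pixels."""
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        deg = _degree_map(skel)
        endpoints = np.argwhere((deg == 1))
        for r, c in endpoints:
            if not skel[r, c]:
                continue
            path = [(r, c)]
            prev = None
            cur = (r, c)
            while True:
                nbs = [p for p in _neighbors(skel, *cur) if p != prev]
                if len(nbs) != 1:
                    break
                prev, cur = cur, nbs[0]
                deg_cur = sum(1 for _ in _neighbors(skel, *cur))
                if deg_cur > 2 or len(path) >= max_len:
                    break
                path.append(cur)
            # a spur ends at a junction before reaching max_len
            if len(path) < max_len and sum(1 for _ in _neighbors(skel, *cur)) > 2:
                for p in path:
                    skel[p] = False
                changed = True
    return skel


def _bfs_farthest(skel: np.ndarray, start: tuple[int, int]):
    """(farthest pixel, predecessor map) by breadth-first search on the
    8-connected skeleton graph."""
    from collections import deque

    prev = {start: None}
    queue = deque([start])
    last = start
    while queue:
        cur = queue.popleft()
        last = cur
        for nb in _neighbors(skel, *cur):
            if nb not in prev:
                prev[nb] = cur
                queue.append(nb)
    return last, prev


def _trace_component(skel: np.ndarray, seed: tuple[int, int]) -> list[tuple[int, int]]:
    """Longest endpoint-to-endpoint path through a thin component.

    Double BFS (graph-diameter heuristic, exact on trees): residual side
    branches that survived spur pruning are left off the path.
    """
    u, _ = _bfs_farthest(skel, seed)
    v, prev = _bfs_farthest(skel, u)
    path = [v]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path


def extract_centerline(mask: np.ndarray, spur_length: int = 10) -> list[np.ndarray]:
    """Skeletonize a segmented mask into ordered per-component polylines.

    Hole-fill -> thinning -> iterative spur pruning (< ``spur_length`` px) ->
    ordered traversal.  Returns a list of (n, 2) arrays in (u, v) = (col, row)
    pixels, longest first; empty list for an empty mask.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    # fill pinholes inside the band; a large enclosed region (a tightly
    # curved catheter) must stay open or the skeleton collapses to a blob
    m = remove_small_holes(m, max_size=100)
    skel = skeletonize(m)
    skel = _prune_spurs(skel, spur_length)
    lab = label(skel, connectivity=2)
    polylines = []
    for i in range(1, lab.max() + 1):
        comp = lab == i
        deg = _degree_map(comp)
        ends = np.argwhere(deg == 1)
        seed = tuple(ends[0]) if len(ends) else tuple(np.argwhere(comp)[0])
        pts = _trace_component(comp, seed)
        polylines.append(np.array([(c, r) for r, c in pts], dtype=float))
    polylines.sort(key=len, reverse=True)
    return polylines


def _tangent(poly: np.ndarray, at_start: bool, k: int = 8) -> np.ndarray:
    """Unit direction of travel at an end of the polyline (into the curve at
    its start, out of the curve at its end)."""
    if at_start:
        seg = poly[: min(k, len(poly))]
        v = seg[-1] - seg[0]
    else:
        seg = poly[-min(k, len(poly)) :]
        v = seg[-1] - seg[0]
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros(2)


def _akima_bridge(a: np.ndarray, b: np.ndarray, support: int = 4) -> np.ndarray:
    """Akima interpolation across the gap between the end of ``a`` and the
    start of ``b``, parameterized by cumulative chord length, 1-px sampling."""
    sup_a = a[-min(support, len(a)) :]
    sup_b = b[: min(support, len(b))]
    pts = np.vstack([sup_a, sup_b])
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    # strictly increasing parameter required
    keep = np.concatenate([[True], np.diff(t) > 1e-9])
    pts, t = pts[keep], t[keep]
    n_a = int(keep[: len(sup_a)].sum())  # surviving support points from side a
    if len(pts) < 3 or n_a < 1 or n_a >= len(pts):
        gap = np.linalg.norm(b[0] - a[-1])
        n = max(2, int(np.ceil(gap)))
        s = np.linspace(0, 1, n + 1)[1:-1]
        return a[-1] + s[:, None] * (b[0] - a[-1])
    interp = Akima1DInterpolator(t, pts, axis=0)
    ta, tb = t[n_a - 1], t[n_a]  # parameters of the gap endpoints
    n = max(2, int(np.ceil(tb - ta)))
    s = np.linspace(ta, tb, n + 1)[1:-1]
    return interp(s)


def fill_gaps(
    components: list[np.ndarray],
    max_gap: float = 50.0,
    max_angle_deg: float = 60.0,
    pixel_spacing: float = 0.154,
) -> CatheterCenterline:
    """Link skeleton components into a single ordered centerline.

    Greedily joins the nearest compatible endpoint pair (gap <= ``max_gap``
    px and both end tangents within ``max_angle_deg`` of the gap chord),
    bridging each gap with Akima cubic Hermite interpolation sampled at 1-px
    spacing.  Unpairable leftovers beyond the gap limit are dropped with a
    warning and the longest chain is returned.
    """
    comps = [np.asarray(c, dtype=float) for c in components if len(c) >= 2]
    if not comps:
        raise ValueError("need at least one component with >= 2 points")
    cos_lim = np.cos(np.deg2rad(max_angle_deg))

    def compatible(a: np.ndarray, b: np.ndarray) -> float | None:
        """Gap length if joining end of a to start of b is admissible."""
        chord = b[0] - a[-1]
        gap = np.linalg.norm(chord)
        if gap > max_gap or gap == 0:
            return None
        u = chord / gap
        ta = _tangent(a, at_start=False)
        tb = _tangent(b, at_start=True)
        if ta @ u < cos_lim or tb @ u < cos_lim:
            return None
        return gap

    while len(comps) > 1:
        best = None
        for i in range(len(comps)):
            for j in range(len(comps)):
                if i == j:
                    continue
                for flip_i in (False, True):
                    for flip_j in (False, True):
                        a = comps[i][::-1] if flip_i else comps[i]
                        b = comps[j][::-1] if flip_j else comps[j]
                        g = compatible(a, b)
                        if g is not None and (best is None or g < best[0]):
                            best = (g, i, j, flip_i, flip_j)
        if best is None:
            warnings.warn(
                "unpairable components beyond gap/angle limits; keeping longest chain",
                stacklevel=2,
            )
            break
        _, i, j, flip_i, flip_j = best
        a = comps[i][::-1] if flip_i else comps[i]
        b = comps[j][::-1] if flip_j else comps[j]
        bridge = _akima_bridge(a, b)
        merged = np.vstack([a, bridge, b]) if len(bridge) else np.vstack([a, b])
        comps = [c for k, c in enumerate(comps) if k not in (i, j)] + [merged]
    longest = max(comps, key=len)
    # drop exact duplicates introduced by bridging
    keep = np.concatenate([[True], np.linalg.norm(np.diff(longest, axis=0), axis=1) > 1e-9])
    return CatheterCenterline(points=longest[keep], pixel_spacing=pixel_spacing)


def clip_to_landmarks(
    centerline: CatheterCenterline,
    p_a: np.ndarray,
    p_b: np.ndarray,
    physical_length_mm: float,
    snap_tolerance: float = 5.0,
) -> CatheterCenterline:
    """Clip the centerline between two landmark points (snapped to the curve).

    The physical landmark separation in mm (e.g. 30 for the standard
    two-marker microcatheter) is stored for the calibration scale constraint.
    """
    pts = centerline.points
    ia = _snap(pts, np.asarray(p_a, float), snap_tolerance)
    ib = _snap(pts, np.asarray(p_b, float), snap_tolerance)
    if ia == ib:
        raise ValueError("landmarks coincide on the centerline")
    lo, hi = min(ia, ib), max(ia, ib)
    sub = pts[lo : hi + 1]
    if ia > ib:
        sub = sub[::-1]
    return CatheterCenterline(
        points=sub.copy(),
        pixel_spacing=centerline.pixel_spacing,
        landmark_indices=(0, len(sub) - 1),
        physical_length_mm=physical_length_mm,
    )


def _snap(pts: np.ndarray, p: np.ndarray, tol: float) -> int:
    d = np.linalg.norm(pts - p, axis=1)
    i = int(np.argmin(d))
    if d[i] > tol:
        raise ValueError(f"landmark {p} is {d[i]:.1f} px from the centerline (> {tol})")
    return i
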