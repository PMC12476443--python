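"""64-dimensional hand-crafted feature bank for candidate events.

For each candidate :class:`~cathcalib.indicators.EventRegion` the features are

* f1-f18   — max/min/mean of the hf, der and cur indicators over the event
  neighborhood, raw (9) and after a 5-px moving average (9);
* f19-f28  — signal statistics of the detrended residual over the
  neighborhood: RMS, kurtosis, skewness, impulse factor, clearance factor,
  crest factor, population std, log variance and two variation metrics;
* f29-f31  — max/mean/min of the Frangi vesselness response (dark ridges,
  scales 1..2 with ratio 0.5, structureness beta2 = 30);
* f32-f43  — max/mean/min of Difference-of-Gaussian (sigma 1 vs 2, kernel
  sizes 10/20) and Laplacian-of-Gaussian (kernel 15, sigma 0.5) responses on
  the original and the bottom-hat-filtered image, each normalized to [0, 1];
* f44-f46  — max/mean/min of the bottom-hat image (disk radius 3);
* f47-f64  — directional sums within an 11x11 patch around the event center,
  along 8 orientations, on a Hough-detected "probable curves" binary map and
  on the hf values masked to those curves, plus the totals.

Image-level responses are computed once per frame (:class:`FrameFeatureCache`)
and sampled per event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d, gaussian_filter, gaussian_laplace, uniform_filter1d
from skimage.draw import line as draw_line
from skimage.filters import frangi as _frangi
from skimage.filters import sobel
from skimage.morphology import dilation as binary_dilation, black_tophat, disk
from skimage.transform import hough_line, hough_line_peaks

from cathcalib.indicators import EventRegion, frame_indicators

__all__ = [
    "FEATURE_NAMES",
    "FrameFeatureCache",
    "signal_stats",
    "indicator_stats",
    "frangi_stats",
    "dog_log_bottomhat_stats",
    "directional_features",
    "assemble_feature_vector",
    "extract_event_features",
    "UNDEFINED",
]

UNDEFINED = np.nan  # sentinel for moments that are undefined (zero variance)

PATCH = 11
N_DIRECTIONS = 8

_IND = ("hf", "der", "cur")
_STAT = ("max", "min", "mean")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{ind}_{st}" for ind in _IND for st in _STAT]
    + [f"{ind}_sm_{st}" for ind in _IND for st in _STAT]
    + [
        "rms",
        "kurtosis",
        "skewness",
        "impulse_factor",
        "clearance_factor",
        "crest_factor",
        "std",
        "log_variance",
        "variation_1",
        "variation_2",
    ]
    + [f"frangi_{st}" for st in _STAT]
    + [f"dog_{st}" for st in _STAT]
    + [f"dog_bh_{st}" for st in _STAT]
    + [f"log_{st}" for st in _STAT]
    + [f"log_bh_{st}" for st in _STAT]
    + [f"bottomhat_{st}" for st in _STAT]
    + [f"dir_curve_{k}" for k in range(N_DIRECTIONS)]
    + ["dir_curve_total"]
    + [f"dir_hf_{k}" for k in range(N_DIRECTIONS)]
    + ["dir_hf_total"]
)
assert len(FEATURE_NAMES) == 64


def _minmax(img: np.ndarray) -> np.ndarray:
    rng = img.max() - img.min()
    if rng < 1e-300:
        return np.zeros_like(img)
    return (img - img.min()) / rng


def _gauss_kernel(sigma: float, size: int) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, size - half, dtype=float)
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def _separable(img: np.ndarray, k: np.ndarray) -> np.ndarray:
    return correlate1d(correlate1d(img, k, axis=0, mode="reflect"), k, axis=1, mode="reflect")


def _hough_curve_map(img: np.ndarray, num_peaks: int = 50) -> np.ndarray:
    """Binary "probable curves" map: Sobel edges -> line Hough -> rasterized
    detected lines kept only where they track edge support."""
    edges = sobel(img)
    thr = edges.mean() + 2 * edges.std()
    edge_bin = edges > thr
    if not edge_bin.any():
        return np.zeros(img.shape, dtype=bool)
    h, theta, dist = hough_line(edge_bin, theta=np.deg2rad(np.arange(-90.0, 90.0)))
    _, angles, dists = hough_line_peaks(
        h, theta, dist, num_peaks=num_peaks, threshold=0.3 * h.max()
    )
    support = binary_dilation(edge_bin, disk(2))
    out = np.zeros(img.shape, dtype=bool)
    nr, nc = img.shape
    diag = int(np.hypot(nr, nc)) + 2
    for ang, d in zip(angles, dists):
        # parametrize the infinite line, clip to the frame, keep edge-supported px
        n = np.array([np.cos(ang), np.sin(ang)])  # (x, y) normal
        p0 = d * n
        t = np.array([-n[1], n[0]])
        a = p0 - diag * t
        b = p0 + diag * t
        rr, cc = draw_line(int(round(a[1])), int(round(a[0])), int(round(b[1])), int(round(b[0])))
        keep = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
        rr, cc = rr[keep], cc[keep]
        sup = support[rr, cc]
        out[rr[sup], cc[sup]] = True
    return out


def _direction_offsets(patch: int = PATCH) -> list[tuple[np.ndarray, np.ndarray]]:
    """Row/col offsets of discrete lines through the patch center for the 8
    orientations 0, 22.5, ..., 157.5 degrees (0 = horizontal)."""
    half = patch // 2
    offs = []
    for k in range(N_DIRECTIONS):
        ang = np.deg2rad(k * 180.0 / N_DIRECTIONS)
        dc, dr = np.cos(ang), np.sin(ang)
        r0, c0 = int(round(-half * dr)), int(round(-half * dc))
        r1, c1 = int(round(half * dr)), int(round(half * dc))
        rr, cc = draw_line(r0 + half, c0 + half, r1 + half, c1 + half)
        offs.append((rr - half, cc - half))
    return offs


_OFFSETS = _direction_offsets()


@dataclass
class FrameFeatureCache:
    """Per-frame image responses shared by every event of the frame.

    ``hf_rows``/``hf_cols`` etc. hold the row-wise and column-wise indicator
    maps; the filter responses are computed lazily on first access.
    """

    frame: np.ndarray
    hf: dict = field(default_factory=dict)
    der: dict = field(default_factory=dict)
    cur: dict = field(default_factory=dict)
    _maps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        img = np.asarray(self.frame, dtype=float)
        self.frame = img
        for axis, data in (("row", img), ("column", img.T)):
            hf, der, cur, _ = frame_indicators(data)
            self.hf[axis], self.der[axis], self.cur[axis] = hf, der, cur

    def response(self, name: str) -> np.ndarray:
        if name in self._maps:
            return self._maps[name]
        img = self.frame
        if name == "bottomhat":
            out = black_tophat(img, disk(3))
        elif name == "frangi":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = _frangi(
                    img, sigmas=(1.0, 1.5, 2.0), beta=0.5, gamma=30.0, black_ridges=True
                )
            out = np.nan_to_num(out)
        elif name in ("dog", "dog_bh"):
            base = img if name == "dog" else self.response("bottomhat")
            g1 = _separable(base, _gauss_kernel(1.0, 10))
            g2 = _separable(base, _gauss_kernel(2.0, 20))
            out = _minmax(g1 - g2)
        elif name in ("log", "log_bh"):
            base = img if name == "log" else self.response("bottomhat")
            # truncate*sigma = 7 px radius -> 15-px kernel at sigma 0.5
            out = _minmax(gaussian_laplace(base, 0.5, mode="reflect", truncate=14.0))
        elif name == "curves":
            out = _hough_curve_map(img)
        elif name == "hf_image":
            # full-frame hf raster: union of row- and column-wise responses
            out = np.maximum(self.hf["row"], self.hf["column"].T)
        else:  # pragma: no cover
            raise KeyError(name)
        self._maps[name] = out
        return out


def _stats3(vals: np.ndarray) -> tuple[float, float, float]:
    return float(vals.max()), float(vals.min()), float(vals.mean())


def indicator_stats(event: EventRegion, hf: np.ndarray, der: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """f1-f18: max/min/mean of each indicator over the event neighborhood,
    raw and after 5-px moving-average smoothing."""
    sl = slice(event.nb_start, event.nb_end + 1)
    if event.nb_end < event.nb_start:
        raise ValueError("empty event span")
    out = []
    for arr in (hf, der, cur):
        out.extend(_stats3(arr[sl]))
    for arr in (hf, der, cur):
        out.extend(_stats3(uniform_filter1d(np.asarray(arr, float), 5)[sl]))
    return np.array(out)


def signal_stats(values: np.ndarray) -> np.ndarray:
    """f19-f28 signal statistics of a 1D sample.

    Moment ratios (kurtosis, skewness) are population-normalized; with zero
    variance they are undefined and returned as the NaN sentinel with a
    warning.  The clearance factor's square root is taken on |x| since
    detrended signals may be negative.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    n = len(x)
    mu = x.mean()
    sigma = x.std()
    xp = np.abs(x).max()
    rms = np.sqrt((x**2).mean())
    if sigma < 1e-300:
        warnings.warn("zero variance: kurtosis/skewness undefined", stacklevel=2)
        kurt = skew = UNDEFINED
        logvar = UNDEFINED
    else:
        kurt = ((x - mu) ** 4).mean() / sigma**4
        skew = ((x - mu) ** 3).mean() / sigma**3
        logvar = np.log(sigma**2)
    mean_abs = np.abs(x).mean()
    impulse = xp / mean_abs if mean_abs > 0 else UNDEFINED
    mean_sqrt = np.sqrt(np.abs(x)).mean()
    clearance = xp / mean_sqrt**2 if mean_sqrt > 0 else UNDEFINED
    crest = xp / rms if rms > 0 else UNDEFINED
    var1 = np.abs(np.diff(x)).sum()
    var2 = abs(np.diff(x).sum())
    return np.array(
        [rms, kurt, skew, impulse, clearance, crest, sigma, logvar, var1, var2]
    )


def _event_pixels(event: EventRegion, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of the event neighborhood in image coordinates."""
    span = np.arange(event.nb_start, event.nb_end + 1)
    if event.axis == "row":
        return np.full_like(span, event.line), span
    return span, np.full_like(span, event.line)


def frangi_stats(cache: FrameFeatureCache, event: EventRegion) -> np.ndarray:
    """f29-f31: max/min/mean Frangi vesselness over the event neighborhood."""
    rr, cc = _event_pixels(event, cache.frame.shape)
    return np.array(_stats3(cache.response("frangi")[rr, cc]))


def dog_log_bottomhat_stats(cache: FrameFeatureCache, event: EventRegion) -> np.ndarray:
    """f32-f46: DoG/LoG stats on original and bottom-hat image + bottom-hat stats."""
    rr, cc = _event_pixels(event, cache.frame.shape)
    out = []
    for name in ("dog", "dog_bh", "log", "log_bh", "bottomhat"):
        out.extend(_stats3(cache.response(name)[rr, cc]))
    return np.array(out)


def directional_features(
    curves: np.ndarray, hf_map: np.ndarray, center: tuple[int, int]
) -> np.ndarray:
    """f47-f64: directional sums in the 11x11 patch around ``center``.

    Eight per-orientation sums plus the total, on the binary curve map and on
    hf masked to the curves.  Patch pixels outside the frame count as zero.
    """
    r0, c0 = center
    nr, nc = curves.shape
    masked_hf = np.where(curves, hf_map, 0.0)
    curve_sums = np.zeros(N_DIRECTIONS)
    hf_sums = np.zeros(N_DIRECTIONS)
    for k, (dr, dc) in enumerate(_OFFSETS):
        rr, cc = r0 + dr, c0 + dc
        keep = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
        rr, cc = rr[keep], cc[keep]
        curve_sums[k] = curves[rr, cc].sum()
        hf_sums[k] = masked_hf[rr, cc].sum()
    return np.concatenate(
        [curve_sums, [curve_sums.sum()], hf_sums, [hf_sums.sum()]]
    )


def assemble_feature_vector(cache: FrameFeatureCache, event: EventRegion) -> np.ndarray:
    """Fixed-order 64-feature vector for one event (deterministic)."""
    axis = event.axis
    hf = cache.hf[axis][event.line]
    der = cache.der[axis][event.line]
    cur = cache.cur[axis][event.line]
    # the line's residual signal over the neighborhood feeds the statistics
    data = cache.frame if axis == "row" else cache.frame.T
    sl = slice(event.nb_start, event.nb_end + 1)
    profile = data[event.line]
    residual = profile - _trend_cached(cache, axis)[event.line]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = signal_stats(residual[sl])
    if axis == "row":
        center = (event.line, event.center)
    else:
        center = (event.center, event.line)
    vec = np.concatenate(
        [
            indicator_stats(event, hf, der, cur),
            stats,
            frangi_stats(cache, event),
            dog_log_bottomhat_stats(cache, event),
            directional_features(cache.response("curves"), cache.response("hf_image"), center),
        ]
    )
    assert len(vec) == 64
    return vec


def _trend_cached(cache: FrameFeatureCache, axis: str) -> np.ndarray:
    key = f"trend_{axis}"
    if key not in cache._maps:
        from cathcalib.indicators import _frame_trend

        data = cache.frame if axis == "row" else cache.frame.T
        cache._maps[key] = _frame_trend(data)
    return cache._maps[key]


def extract_event_features(
    frame: np.ndarray, events: list[EventRegion]
) -> tuple[np.ndarray, FrameFeatureCache]:
    """Feature matrix (n_events, 64) for all events of one frame."""
    cache = FrameFeatureCache(frame)
    if not events:
        return np.zeros((0, 64)), cache
    mat = np.vstack([assemble_feature_vector(cache, ev) for ev in events])
    return mat, cache
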