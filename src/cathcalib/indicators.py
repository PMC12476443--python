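"""Per-line indicators for catheter candidate detection.

A catheter crosses an image row or column as a sharp negative deflection a few
pixels wide.  Three 1D indicators respond to that signature:

* ``hf`` — high-frequency energy: the square of the sum of the first three
  detail-level reconstructions of a 3-level Daubechies-4 wavelet decomposition;
* ``der`` — the squared output of a smoothing differentiator applied to the
  detrended signal (signal minus its wavelet approximation);
* ``cur`` — a local-concavity score: within a sliding 7-px window a weighted
  quadratic fit ``y ~ theta2*(-w^2) + theta0`` of the *negative part* of the
  detrended signal; the product ``theta2*theta0`` peaks at concave dips.

The three indicator maps are combined per 5-px window (weights 0.8/0.1/0.1 on
windowed-max hf and windowed-mean der/cur), multiplied by the hf map, and
robustly normalized per frame (99.5th-percentile scale, clipped to [0, 1]);
candidate pixels exceed a fixed threshold (0.1) on either the row-wise or
column-wise map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import correlate1d, grey_dilation, maximum_filter1d, uniform_filter1d
from scipy.signal import savgol_coeffs

__all__ = [
    "IndicatorSet",
    "EventRegion",
    "CandidateMask",
    "dwt_trend",
    "highfreq_indicator",
    "derivative_indicator",
    "curvature_indicator",
    "line_indicators",
    "frame_indicators",
    "combine_indicators",
    "candidate_mask",
    "otsu_threshold",
    "DEFAULT_WEIGHTS",
    "DEFAULT_THRESHOLD",
]

_WAVELET = "db4"
_LEVELS = 3
_MIN_LEN = 16

# group-delay-6 linear-phase smoothing differentiator (13-tap Savitzky-Golay,
# cubic); applied causally its output is the recentred derivative at k+6
_DER_DELAY = 6
_DER_TAPS = savgol_coeffs(13, 3, deriv=1, delta=1.0, use="conv")[::-1]

# 7-px curvature window: symmetric center-peaked tent from the 1:(-1/h):(1/h)
# ramp with h=3, mirrored around the center
CURVATURE_WINDOW = 7
_CUR_WEIGHTS = np.array([1 / 3, 2 / 3, 1.0, 1.0, 1.0, 2 / 3, 1 / 3])

DEFAULT_WEIGHTS = (0.8, 0.1, 0.1)
DEFAULT_THRESHOLD = 0.1
NEIGHBORHOOD = 5  # px, along-line dilation of candidate runs (max catheter width)


@dataclass
class IndicatorSet:
    """Per-sample indicator values along one line (row or column) of a frame."""

    hf: np.ndarray
    der: np.ndarray
    cur: np.ndarray
    trend: np.ndarray
    residual: np.ndarray
    axis: str = "row"
    index: int = 0


@dataclass(frozen=True)
class EventRegion:
    """A maximal candidate run on one line, with its +/-5 px neighborhood."""

    axis: str  # "row" or "column"
    line: int
    start: int  # inclusive
    end: int  # inclusive
    nb_start: int
    nb_end: int

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CandidateMask:
    """Binary candidate raster plus the per-line event runs that produced it."""

    mask: np.ndarray
    events: list[EventRegion]


def _check_profile(sig: np.ndarray) -> np.ndarray:
    sig = np.asarray(sig, dtype=float)
    if sig.ndim != 1 or len(sig) < _MIN_LEN:
        raise ValueError(f"profile must be 1D with length >= {_MIN_LEN}")
    return sig


def dwt_trend(profile: np.ndarray, levels: int = _LEVELS) -> np.ndarray:
    """Low-frequency trend: reconstruction from the level-`levels` db4 approximation."""
    sig = _check_profile(profile)
    coeffs = pywt.wavedec(sig, _WAVELET, level=levels, mode="symmetric")
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, _WAVELET, mode="symmetric")[: len(sig)]


def _detail_reconstructions(sig: np.ndarray, levels: int = _LEVELS) -> list[np.ndarray]:
    """Full-length single-branch reconstructions D_j for detail levels 1..levels."""
    coeffs = pywt.wavedec(sig, _WAVELET, level=levels, mode="symmetric")
    out = []
    for j in range(1, levels + 1):
        sel = [np.zeros_like(c) for c in coeffs]
        sel[-j] = coeffs[-j]  # level j details are the j-th entry from the end
        out.append(pywt.waverec(sel, _WAVELET, mode="symmetric")[: len(sig)])
    return out


def highfreq_indicator(profile: np.ndarray) -> np.ndarray:
    """hf(t) = (D1(t) + D2(t) + D3(t))^2 from the db4 decomposition."""
    sig = _check_profile(profile)
    details = _detail_reconstructions(sig)
    return np.sum(details, axis=0) ** 2


def derivative_indicator(residual: np.ndarray) -> np.ndarray:
    """Squared, recentred output of the smoothing differentiator on the residual.

    The 13-tap linear-phase filter has group delay 6; its causal output y is
    advanced by 6 samples (der(k) = y(k+6)^2) so the response aligns with the
    input; boundary samples are zero-padded.
    """
    res = np.asarray(residual, dtype=float)
    y = np.convolve(res, _DER_TAPS, mode="full")[: len(res)]  # causal filtering
    out = np.zeros_like(res)
    out[: len(res) - _DER_DELAY] = y[_DER_DELAY:] ** 2
    return out


def _curvature_filters(window: int) -> tuple[np.ndarray, np.ndarray]:
    """Rows of (X^T W X)^-1 X^T W as correlation kernels for theta2 and theta0."""
    half = window // 2
    w = np.arange(-half, half + 1, dtype=float)
    x = np.column_stack([-(w**2), np.ones_like(w)])
    if window == CURVATURE_WINDOW:
        dw = _CUR_WEIGHTS
    else:
        ramp = 1 - np.abs(w) / (half + 1)
        dw = ramp / ramp.max()
    m = np.linalg.solve(x.T @ (dw[:, None] * x), x.T * dw)  # 2 x window
    return m[0], m[1]


def curvature_indicator(residual: np.ndarray, window: int = CURVATURE_WINDOW) -> np.ndarray:
    """cur(k) = theta2(k) * theta0(k) from a weighted quadratic fit of the
    negative part of the residual in a sliding window; clamped to >= 0."""
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be odd and >= 5")
    res = np.asarray(residual, dtype=float)
    if window >= len(res):
        raise ValueError("window must be shorter than the signal")
    neg = np.minimum(res, 0.0)
    k2, k0 = _curvature_filters(window)
    theta2 = correlate1d(neg, k2, mode="constant")
    theta0 = correlate1d(neg, k0, mode="constant")
    return np.maximum(theta2 * theta0, 0.0)


def line_indicators(profile: np.ndarray, axis: str = "row", index: int = 0) -> IndicatorSet:
    """All three indicators plus trend/residual for one line profile."""
    sig = _check_profile(profile)
    trend = dwt_trend(sig)
    residual = sig - trend
    return IndicatorSet(
        hf=highfreq_indicator(sig),
        der=derivative_indicator(residual),
        cur=curvature_indicator(residual),
        trend=trend,
        residual=residual,
        axis=axis,
        index=index,
    )


# ---------------------------------------------------------------------------
# vectorized whole-frame versions (axis=1 of a 2D array)

def _frame_trend(img: np.ndarray) -> np.ndarray:
    coeffs = pywt.wavedec(img, _WAVELET, level=_LEVELS, mode="symmetric", axis=1)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, _WAVELET, mode="symmetric", axis=1)[:, : img.shape[1]]


def frame_indicators(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(hf, der, cur, residual) computed along every row of ``img`` at once."""
    img = np.asarray(img, dtype=float)
    trend = _frame_trend(img)
    residual = img - trend
    hf = residual**2  # sum of all detail branches == signal - approximation
    full = np.apply_along_axis(
        lambda r: np.convolve(r, _DER_TAPS, mode="full")[: img.shape[1]], 1, residual
    )
    der = np.zeros_like(residual)
    der[:, : img.shape[1] - _DER_DELAY] = full[:, _DER_DELAY:] ** 2
    neg = np.minimum(residual, 0.0)
    k2, k0 = _curvature_filters(CURVATURE_WINDOW)
    theta2 = correlate1d(neg, k2, axis=1, mode="constant")
    theta0 = correlate1d(neg, k0, axis=1, mode="constant")
    cur = np.maximum(theta2 * theta0, 0.0)
    return hf, der, cur, residual


NORM_PERCENTILE = 99.5  # robust scale anchor of the combined map


def combine_indicators(
    hf: np.ndarray,
    der: np.ndarray,
    cur: np.ndarray,
    window: int = 5,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    norm_percentile: float = NORM_PERCENTILE,
) -> np.ndarray:
    """Weighted per-window combination, gated by hf, robustly normalized.

    score = w_hf * windowed-max(hf) + w_der * windowed-mean(der)
          + w_cur * windowed-mean(cur);  map = score * hf, scaled to [0, 1].

    The scale is the map's ``norm_percentile``-th percentile (clipping above
    it) rather than the raw maximum: the map grows with the 4th power of a
    dip's depth, so a handful of extreme pixels — radio-opaque marker blobs —
    would otherwise set the scale of the whole frame and push ordinary
    catheter responses below any fixed threshold.

    Works on 1D profiles or on 2D stacks (windowing along the last axis).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"weights must sum to 1 (got {w.sum()})")
    hf = np.asarray(hf, dtype=float)
    score = (
        w[0] * maximum_filter1d(hf, window, axis=-1)
        + w[1] * uniform_filter1d(np.asarray(der, float), window, axis=-1)
        + w[2] * uniform_filter1d(np.asarray(cur, float), window, axis=-1)
    )
    out = score * hf
    out = out - out.min()
    mx = out.max()
    if mx < 1e-18:  # numerically flat map (e.g. constant frame)
        return np.zeros_like(out)
    scale = np.percentile(out, norm_percentile)
    if scale < 1e-12 * mx:
        scale = mx
    return np.clip(out / scale, 0.0, 1.0)


def _runs(bools: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as (start, end) inclusive."""
    idx = np.flatnonzero(bools)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def candidate_mask(
    frame: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    neighborhood: int = NEIGHBORHOOD,
) -> CandidateMask:
    """Detect catheter candidate regions on every row and column of a frame.

    The combined indicator map is computed row-wise and column-wise (each
    normalized per frame); a pixel is a candidate where either map exceeds
    ``threshold``.  Each per-line candidate run keeps a ``neighborhood``-px
    margin along its line as an :class:`EventRegion`; the binary mask takes
    the same margin both horizontally and vertically (catheter widths do not
    exceed five pixels, so the cross-line margin covers the full width).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError("frame must be 2D, at least 32x32")

    events: list[EventRegion] = []
    hits_union = np.zeros(img.shape, dtype=bool)

    for axis, data in (("row", img), ("column", img.T)):
        hf, der, cur, _ = frame_indicators(data)
        cmap = combine_indicators(hf, der, cur, weights=weights)
        hits = cmap > threshold
        n = data.shape[1]
        for line in range(data.shape[0]):
            for start, end in _runs(hits[line]):
                nb0 = max(0, start - neighborhood)
                nb1 = min(n - 1, end + neighborhood)
                events.append(EventRegion(axis, line, start, end, nb0, nb1))
        hits_union |= hits if axis == "row" else hits.T

    mask = grey_dilation(
        hits_union, size=(2 * neighborhood + 1, 2 * neighborhood + 1)
    ).astype(bool)
    return CandidateMask(mask=mask, events=events)


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu threshold of a value sample over a ``bins``-bin histogram.

    Maximizes the between-class variance over all cut points; raises on
    constant input.
    """
    vals = np.asarray(values, dtype=float).ravel()
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ValueError("degenerate input: all values equal")
    hist, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * w0 - mu) ** 2 / (w0 * (1 - w0))
    var_between[~np.isfinite(var_between)] = -np.inf
    return float(centers[int(np.argmax(var_between[:-1]))])
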