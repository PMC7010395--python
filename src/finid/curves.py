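"""Planar-curve primitives for contour scale-space analysis.

A fin contour, or any region boundary, is represented as an ordered polyline
:class:`PlanarCurve`.  The two coordinate functions ``x(u)`` and ``y(u)`` are
treated as independent 1-D signals; smoothing them with zero-mean Gaussians at
two scales and taking the squared difference yields a band-pass corner
response along the curve.  Local maxima of that response, ranked by peak
prominence, provide the boundary keypoints used both for fin-candidate
generation and for biometric subsection encoding.

Conventions
-----------
* Scales (``sigma``) are expressed in *samples* of the (uniformly resampled)
  curve, so responses are comparable across curves of equal sample count.
* Closed curves are handled circularly; open curves use reflection padding.
* Gaussian kernels are truncated at ``4*sigma`` and renormalised to unit mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlanarCurve",
    "CornerResponse",
    "KeypointSet",
    "resample_curve",
    "gaussian_smooth",
    "dog_response",
    "find_keypoints",
]


class DegenerateCurveError(ValueError):
    """Raised when a curve has no usable geometry (zero length, too few points)."""


@dataclass(frozen=True)
class PlanarCurve:
    """An ordered planar polyline in pixel units.

    For closed curves the wrap from the last point back to the first is
    implicit: the first vertex is *not* repeated at the end.
    """

    points: np.ndarray  # (n, 2) float array of (x, y)
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        if len(pts) < 3:
            raise DegenerateCurveError("a curve needs at least 3 points")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive duplicate points are not allowed")
        if self.closed and np.all(pts[0] == pts[-1]):
            raise ValueError("closed curve must not repeat its first point")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def segment_lengths(self) -> np.ndarray:
        """Lengths of polyline segments (including the wrap for closed curves)."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    def arc_length(self) -> float:
        return float(self.segment_lengths().sum())

    def reversed(self) -> "PlanarCurve":
        return PlanarCurve(self.points[::-1].copy(), closed=self.closed)

    def transformed(self, *, angle: float = 0.0, scale: float = 1.0,
                    offset=(0.0, 0.0)) -> "PlanarCurve":
        """Rigid/similarity transform: rotate by ``angle`` (radians), scale,
        then translate."""
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        pts = scale * self.points @ rot.T + np.asarray(offset, dtype=float)
        return PlanarCurve(pts, closed=self.closed)


@dataclass(frozen=True)
class CornerResponse:
    """Per-vertex DoG corner response D(u, sigma) of a planar curve."""

    values: np.ndarray
    sigma: float
    m: float
    closed: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals < -1e-12):
            raise ValueError("corner response must be nonnegative")
        object.__setattr__(self, "values", np.maximum(vals, 0.0))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class KeypointSet:
    """Vertex indices of prominence-ranked response maxima (descending)."""

    indices: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        prom = np.asarray(self.prominences, dtype=float)
        if len(idx) != len(prom):
            raise ValueError("indices and prominences must have equal length")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("keypoint indices must be unique")
        if np.any(np.diff(prom) > 1e-12):
            raise ValueError("prominences must be nonincreasing")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "prominences", prom)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _cumulative_arclength(curve: PlanarCurve) -> np.ndarray:
    seg = curve.segment_lengths()
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_curve(curve: PlanarCurve, n_samples: int) -> PlanarCurve:
    """Resample a curve to ``n_samples`` vertices uniformly spaced in arc length.

    Open curves keep both endpoints exactly; closed curves keep the first
    vertex as the starting point and distribute samples over the full
    perimeter (no repeated endpoint).
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    total = curve.arc_length()
    if total <= 0.0:
        raise DegenerateCurveError("cannot resample a zero-length curve")

    cum = _cumulative_arclength(curve)
    pts = curve.points
    if curve.closed:
        pts = np.vstack([pts, pts[:1]])
        t = np.arange(n_samples) * (total / n_samples)
    else:
        t = np.linspace(0.0, total, n_samples)
    x = np.interp(t, cum, pts[:, 0])
    y = np.interp(t, cum, pts[:, 1])
    out = np.column_stack([x, y])
    if not curve.closed:
        out[0] = curve.points[0]
        out[-1] = curve.points[-1]
    # collapse numerically-identical consecutive samples (can only happen for
    # pathological inputs); nudge by interpolation parameter epsilon instead
    return PlanarCurve(out, closed=curve.closed)


# ---------------------------------------------------------------------------
# Gaussian smoothing and the DoG corner response
# ---------------------------------------------------------------------------

def _gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete zero-mean Gaussian, truncated at 4*sigma, unit mass."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = max(1, int(np.ceil(4.0 * sigma)))
    u = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (u / sigma) ** 2)
    return k / k.sum()


def _smooth_signal(values: np.ndarray, sigma: float, closed: bool) -> np.ndarray:
    """Convolve a 1-D signal with a truncated Gaussian.

    Closed signals are padded circularly.  Open signals use odd (antisymmetric)
    reflection about the end samples, which preserves both constants and
    linear ramps: a straight curve stays exactly straight, so open ends add no
    spurious corner response.
    """
    kernel = _gaussian_kernel(sigma)
    radius = (len(kernel) - 1) // 2
    if closed:
        pad = np.pad(values, radius, mode="wrap")
    else:
        pad = np.pad(values, radius, mode="reflect", reflect_type="odd")
    return np.convolve(pad, kernel, mode="valid")


def gaussian_smooth(curve: PlanarCurve, sigma: float) -> PlanarCurve:
    """Smooth x(u) and y(u) independently with a zero-mean Gaussian of scale
    ``sigma`` (in samples)."""
    x = _smooth_signal(curve.x, sigma, curve.closed)
    y = _smooth_signal(curve.y, sigma, curve.closed)
    return PlanarCurve(np.column_stack([x, y]), closed=curve.closed)


def dog_response(curve: PlanarCurve, sigma: float, m: float) -> CornerResponse:
    """Difference-of-Gaussian corner response of a planar curve.

    ``D(u) = [G(m*sigma)*x - G(sigma)*x]^2 + [G(m*sigma)*y - G(sigma)*y]^2``

    Acts as a band-pass filter on contour shape: small ``sigma`` localises
    corners precisely while larger ``m`` emphasises globally salient bends.
    """
    if sigma <= 0 or m <= 0:
        raise ValueError("sigma and m must be positive")
    if m == 1.0:
        warnings.warn("m=1 gives an identically zero response", stacklevel=2)
    dx = _smooth_signal(curve.x, m * sigma, curve.closed) - \
        _smooth_signal(curve.x, sigma, curve.closed)
    dy = _smooth_signal(curve.y, m * sigma, curve.closed) - \
        _smooth_signal(curve.y, sigma, curve.closed)
    return CornerResponse(dx ** 2 + dy ** 2, sigma=sigma, m=m, closed=curve.closed)


# ---------------------------------------------------------------------------
# prominence-ranked keypoints
# ---------------------------------------------------------------------------

def _local_maxima(values: np.ndarray, closed: bool) -> np.ndarray:
    """Indices of local maxima; plateaus contribute their first index."""
    n = len(values)
    if closed:
        prev = np.roll(values, 1)
        nxt = np.roll(values, -1)
        candidates = np.flatnonzero((values > prev) & (values >= nxt))
        maxima = []
        for i in candidates:
            # walk forward over any plateau: must eventually drop, not rise
            j = (i + 1) % n
            steps = 0
            while values[j] == values[i] and steps < n:
                j = (j + 1) % n
                steps += 1
            if steps >= n:  # constant signal
                return np.array([], dtype=int)
            if values[j] < values[i]:
                maxima.append(i)
        return np.asarray(maxima, dtype=int)
    maxima = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j + 1 < n and values[j + 1] < values[i]:
                maxima.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(maxima, dtype=int)


def _prominence_open(values: np.ndarray, peak: int) -> float:
    """Prominence with the signal-end rule: an interval that reaches the end
    of the signal contributes a reference minimum of zero."""
    v = values[peak]
    n = len(values)
    # left interval: up to the nearest strictly higher sample
    i = peak - 1
    min_l = v
    hit_end = True
    while i >= 0:
        if values[i] > v:
            hit_end = False
            break
        min_l = min(min_l, values[i])
        i -= 1
    if hit_end:
        min_l = 0.0
    # right interval
    i = peak + 1
    min_r = v
    hit_end = True
    while i < n:
        if values[i] > v:
            hit_end = False
            break
        min_r = min(min_r, values[i])
        i += 1
    if hit_end:
        min_r = 0.0
    return v - max(min_l, min_r)


def _prominence_closed(values: np.ndarray, peak: int) -> float:
    """Circular prominence: walk both ways around the cycle to the nearest
    strictly higher sample; a closed signal has no ends."""
    v = values[peak]
    n = len(values)
    min_l = v
    i = (peak - 1) % n
    steps = 0
    while steps < n - 1 and values[i] <= v:
        min_l = min(min_l, values[i])
        i = (i - 1) % n
        steps += 1
    if steps == n - 1:  # global maximum: reference is the global minimum
        return v - values.min()
    min_r = v
    i = (peak + 1) % n
    steps = 0
    while steps < n - 1 and values[i] <= v:
        min_r = min(min_r, values[i])
        i = (i + 1) % n
        steps += 1
    return v - max(min_l, min_r)


def find_keypoints(response: CornerResponse, n: int) -> KeypointSet:
    """Select up to ``n`` keypoints as the most prominent local maxima of a
    corner response.

    Prominence of a peak is its height above the larger of the minima of its
    two flanking intervals (each interval extends to the nearest strictly
    higher sample).  For open signals an interval that reaches the signal end
    uses a reference minimum of zero; closed signals are circular.  Equal
    prominences are broken by lower vertex index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values = response.values
    peaks = _local_maxima(values, response.closed)
    if len(peaks) == 0:
        return KeypointSet(np.array([], dtype=int), np.array([], dtype=float))
    prom_fn = _prominence_closed if response.closed else _prominence_open
    proms = np.array([prom_fn(values, int(p)) for p in peaks])
    # numerically constant (or numerically zero) signals produce maxima with
    # prominences at the float-noise level; suppress them.  The absolute term
    # is far below any meaningful response on pixel-unit curves.
    floor = 1e-9 * max(float(np.abs(values).max()), 1.0)
    keep = proms > floor
    peaks, proms = peaks[keep], proms[keep]
    if len(peaks) == 0:
        return KeypointSet(np.array([], dtype=int), np.array([], dtype=float))
    # sort by prominence descending, ties by lower index
    order = np.lexsort((peaks, -proms))[:n]
    return KeypointSet(peaks[order], proms[order])
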