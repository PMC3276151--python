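"""Outline morphometrics for the posterior lobe.

Raw outlines are ordered coordinate traces of a lobe, closed by an
artificial baseline between the trace's two endpoints (where the lateral
plate meets the lobe).  The pipeline is

1. :func:`standardize_outline` — close the trace, rotate the baseline
   horizontal, enforce a single handedness (clockwise traversal, i.e.
   negative signed area) with the lobe above the baseline, and put the
   polygon's area centroid at the origin;
2. :func:`efa_coefficients` — Kuhl–Giardina elliptic Fourier analysis of
   the closed loop, treating x and y independently as functions of
   contour length; 25 harmonics give a 100-number shape descriptor;
3. :func:`shape_pca` — principal components of the descriptors across a
   set of outlines (the mapped trait is the first component);
4. :func:`size_metrics` — area, and height/width measured as the total
   chord length of the vertical/horizontal line through the centroid.

No size or orientation normalization is applied to the Fourier
coefficients: outlines are standardized geometrically beforehand, and the
constant terms are excluded because the loops are centroid-centered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = [
    "RawOutline",
    "StandardOutline",
    "EFACoefficients",
    "ShapeSpace",
    "SizeMetrics",
    "standardize_outline",
    "efa_coefficients",
    "efa_reconstruct",
    "shape_pca",
    "size_metrics",
]


def _as_points(obj):
    pts = np.asarray(obj.points if hasattr(obj, "points") else obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("an outline is an (n, 2) array of coordinates")
    return pts


@dataclass(frozen=True)
class RawOutline:
    """An ordered open trace of one lobe; the artificial baseline is the
    implicit segment from the last point back to the first."""

    points: np.ndarray
    outline_id: str = "outline"
    side: str = "left"
    closed: bool = False

    def __post_init__(self):
        pts = _as_points(self.points)
        if len(pts) < 3:
            raise ValueError("an outline needs at least 3 points")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValueError("outline contains consecutive duplicate points")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class StandardOutline:
    """A standardized closed loop: baseline horizontal, clockwise traversal,
    lobe above the baseline, area centroid at the origin.

    ``points`` holds the open-trace vertices; the baseline is the closing
    segment ``(len(points)-1, 0)``.  ``flagged`` marks outlines whose
    closed polygon self-intersects (kept, but untrustworthy).
    """

    points: np.ndarray
    outline_id: str = "outline"
    side: str = "left"
    flagged: bool = False

    def __post_init__(self):
        object.__setattr__(self, "points", _as_points(self.points))

    @property
    def baseline(self):
        return (len(self.points) - 1, 0)

    def closed_points(self):
        return np.vstack([self.points, self.points[:1]])


def _signed_area(pts):
    x, y = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y2 - x2 * y))


def _area_centroid(pts):
    x, y = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y2 - x2 * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-300:
        raise ValueError("degenerate outline: zero enclosed area")
    cx = np.sum((x + x2) * cross) / (6.0 * a)
    cy = np.sum((y + y2) * cross) / (6.0 * a)
    return np.array([cx, cy])


def standardize_outline(raw, baseline=None):
    """Put an outline into the standard configuration.

    ``baseline`` gives the two vertex indices of the artificial-baseline
    endpoints (default: first and last points of the trace).  The
    transform is rigid plus at most one mirror, so shape is untouched;
    repeated application is the identity to rounding error.
    """
    pts = _as_points(raw)
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("an outline needs at least 3 distinct points")
    b0, b1 = (0, len(pts) - 1) if baseline is None else baseline
    if not (0 <= b0 < len(pts) and 0 <= b1 < len(pts)):
        raise ValueError("baseline endpoints must be vertex indices of the outline")

    v = pts[b1] - pts[b0]
    if np.hypot(*v) == 0.0:
        raise ValueError("baseline endpoints coincide")
    theta = np.arctan2(v[1], v[0])
    c, s = np.cos(-theta), np.sin(-theta)
    pts = pts @ np.array([[c, -s], [s, c]]).T
    if _signed_area(pts) > 0:  # counterclockwise: mirror to fix handedness
        pts = pts * np.array([1.0, -1.0])
    centroid = _area_centroid(pts)
    if centroid[1] < pts[b0, 1]:  # lobe below baseline: half turn
        pts = -pts
        centroid = -centroid
    pts = pts - _area_centroid(pts)

    flagged = False
    if not Polygon(pts).is_valid:
        flagged = True
        warnings.warn(
            f"outline {getattr(raw, 'outline_id', '?')} self-intersects after closure",
            stacklevel=2,
        )
    return StandardOutline(
        points=pts,
        outline_id=getattr(raw, "outline_id", "outline"),
        side=getattr(raw, "side", "left"),
        flagged=flagged,
    )


@dataclass(frozen=True)
class EFACoefficients:
    """Elliptic Fourier descriptors of one closed outline.

    ``harmonics`` is an (n, 4) array of (a_i, b_i, c_i, d_i); ``dc`` holds
    the constant terms (A0, C0), computed but excluded from the 4n
    descriptor because outlines are centroid-centered.  ``perimeter`` is
    the total contour length T.
    """

    harmonics: np.ndarray
    perimeter: float
    dc: tuple = (0.0, 0.0)
    outline_id: str = "outline"

    def __post_init__(self):
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or not np.all(np.isfinite(h)):
            raise ValueError("harmonics must be a finite (n, 4) array")
        object.__setattr__(self, "harmonics", h)

    @property
    def n_harmonics(self):
        return len(self.harmonics)

    def descriptor(self):
        """The flat 4n coefficient vector (a1, b1, c1, d1, a2, ...)."""
        return self.harmonics.ravel().copy()


def efa_coefficients(outline, n=25):
    """Kuhl–Giardina elliptic Fourier coefficients of a closed outline.

    The contour is parameterized by cumulative chord length; x(t) and y(t)
    are each expanded independently.  The exact piecewise-linear integrals
    over the polygon's segments are used, so the result is deterministic
    in the vertex list.
    """
    if n < 1:
        raise ValueError("need at least one harmonic")
    pts = _as_points(outline)
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0.0):
        raise ValueError("outline contains zero-length segments")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValueError("outline has zero perimeter")

    k = np.arange(1, n + 1)[:, None]
    w = 2.0 * np.pi * k / T
    dcos = np.cos(w * t[1:]) - np.cos(w * t[:-1])
    dsin = np.sin(w * t[1:]) - np.sin(w * t[:-1])
    f = T / (2.0 * (k.ravel() ** 2) * np.pi**2)
    sx, sy = d[:, 0] / dt, d[:, 1] / dt
    a = f * (dcos @ sx)
    b = f * (dsin @ sx)
    c = f * (dcos @ sy)
    dd = f * (dsin @ sy)

    # constant terms: exact contour-length averages of the piecewise-linear
    # x(t), y(t) (trapezoid rule is exact per chord)
    a0 = float(np.sum(dt * (closed[:-1, 0] + closed[1:, 0]) / 2.0) / T)
    c0 = float(np.sum(dt * (closed[:-1, 1] + closed[1:, 1]) / 2.0) / T)
    return EFACoefficients(
        harmonics=np.column_stack([a, b, c, dd]),
        perimeter=float(T),
        dc=(a0, c0),
        outline_id=getattr(outline, "outline_id", "outline"),
    )


def efa_reconstruct(coeffs, m=256, n=None, include_dc=True):
    """Sample the truncated Fourier series at m equal parameter steps.

    ``n`` restricts the reconstruction to the first n harmonics (default:
    all stored).  Returns a :class:`StandardOutline` starting at the
    series' t=0 point.
    """
    if m < 8:
        raise ValueError("need at least 8 reconstruction points")
    h = coeffs.harmonics if n is None else coeffs.harmonics[:n]
    T = coeffs.perimeter
    t = np.linspace(0.0, T, m, endpoint=False)
    k = np.arange(1, len(h) + 1)[:, None]
    phase = 2.0 * np.pi * k * t[None, :] / T
    cosp, sinp = np.cos(phase), np.sin(phase)
    x = h[:, 0] @ cosp + h[:, 1] @ sinp
    y = h[:, 2] @ cosp + h[:, 3] @ sinp
    if include_dc:
        x = x + coeffs.dc[0]
        y = y + coeffs.dc[1]
    return StandardOutline(points=np.column_stack([x, y]), outline_id=coeffs.outline_id)


@dataclass
class ShapeSpace:
    """Principal components of a set of shape descriptors.

    Scores of the fitting set, loadings (components x descriptors), the
    per-component variance-explained fractions (they sum to 1), and the
    column means used for centering.  ``prefix`` labels components in
    output tables ("s" for a strain-diversity analysis, "m" for a mapping
    analysis).
    """

    loadings: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    mean: np.ndarray
    prefix: str = "m"

    @property
    def n_components(self):
        return self.loadings.shape[0]

    def component_names(self):
        return [f"{self.prefix}PC{i + 1}" for i in range(self.n_components)]

    def transform(self, X):
        """Scores of new descriptor rows in this shape space."""
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings.T


def shape_pca(X, sign_reference=None, prefix="m"):
    """PCA of a descriptor matrix (outlines x coefficients).

    Components are ordered by variance explained.  Signs are fixed
    deterministically: if ``sign_reference`` is a row index, each
    component is oriented so that outline scores nonnegatively; otherwise
    the loading of largest magnitude is made positive.  Constant
    descriptor columns simply contribute nothing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D matrix with at least two outlines")
    if np.any(~np.isfinite(X)):
        raise ValueError("descriptor matrix contains missing or non-finite values")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = min(len(X) - 1, X.shape[1])
    U, S, Vt = U[:, :r], S[:r], Vt[:r]
    total = float(np.sum(S**2))
    fractions = S**2 / total if total > 0 else np.zeros(r)
    scores = U * S
    for i in range(r):
        if sign_reference is not None:
            flip = scores[sign_reference, i] < 0
        else:
            flip = Vt[i, np.argmax(np.abs(Vt[i]))] < 0
        if flip:
            Vt[i] = -Vt[i]
            scores[:, i] = -scores[:, i]
    return ShapeSpace(
        loadings=Vt, scores=scores, variance_fractions=fractions, mean=mean, prefix=prefix
    )


@dataclass(frozen=True)
class SizeMetrics:
    """Area, height, width and H:W of one standardized outline."""

    area: float
    height: float
    width: float

    @property
    def hw(self):
        return self.height / self.width


def size_metrics(outline):
    """Measure a standardized outline.

    Area is the shoelace area of the closed polygon (the region bounded by
    the artificial baseline is included).  Height (width) is the total
    chord length of the vertical (horizontal) line through the centroid —
    summed over multiple crossings for non-convex outlines.
    """
    pts = _as_points(outline)
    poly = Polygon(pts)
    area = abs(_signed_area(pts if not np.allclose(pts[0], pts[-1]) else pts[:-1]))
    if not poly.is_valid:
        # repair small self-crossings so the chord intersections are defined
        poly = poly.buffer(0)
        if poly.is_empty:
            raise ValueError("outline polygon could not be repaired for measurement")
    minx, miny, maxx, maxy = poly.bounds
    pad = max(maxx - minx, maxy - miny)
    height = poly.intersection(LineString([(0.0, miny - pad), (0.0, maxy + pad)])).length
    width = poly.intersection(LineString([(minx - pad, 0.0), (maxx + pad, 0.0)])).length
    if height == 0.0 or width == 0.0:
        raise ValueError("centroid chord misses the outline: degenerate or non-centered polygon")
    return SizeMetrics(area=float(area), height=float(height), width=float(width))
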