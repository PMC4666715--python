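"""Small geometric utilities shared by the synthetic generator and the
section-based measurements: profile resampling, crease detection and the
folding-angle fit, and polygon area."""

from __future__ import annotations

import numpy as np
from shapely.geometry import LinearRing, Polygon

__all__ = [
    "resample_polyline",
    "profile_curvature",
    "fit_folding_angle",
    "polygon_area",
]


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample an ordered 2D polyline at uniform arc-length ``step``."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (N, 2) polyline with N >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate polyline with zero length")
    si = np.arange(0.0, s[-1] + step / 2, step)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


def _smooth1d(x: np.ndarray, sigma_samples: float) -> np.ndarray:
    if sigma_samples <= 0:
        return x
    n = int(np.ceil(4 * sigma_samples))
    k = np.exp(-0.5 * (np.arange(-n, n + 1) / sigma_samples) ** 2)
    k /= k.sum()
    # reflect-pad so endpoints are not pulled toward zero
    xp = np.concatenate([x[n:0:-1], x, x[-2 : -n - 2 : -1]])
    return np.convolve(xp, k, mode="valid")


def profile_curvature(points: np.ndarray, step: float = 0.5, smooth_um: float = 1.0):
    """Signed curvature of a resampled 2D profile.

    The profile is expected ordered with the second coordinate pointing
    *outward* (away from the tissue); a concave fold (crease) then has
    positive curvature. Returns ``(resampled points, kappa)``.
    """
    rs = resample_polyline(points, step)
    x = _smooth1d(rs[:, 0], smooth_um / step)
    y = _smooth1d(rs[:, 1], smooth_um / step)
    dx, dy = np.gradient(x, step), np.gradient(y, step)
    ddx, ddy = np.gradient(dx, step), np.gradient(dy, step)
    denom = (dx**2 + dy**2) ** 1.5
    denom[denom == 0] = np.inf
    kappa = (dx * ddy - dy * ddx) / denom
    # orient: treat curvature sign so a valley in 'outward' coordinate is positive
    # (traversal direction flips the sign; normalise by overall x direction)
    if x[-1] < x[0]:
        kappa = -kappa
    return np.column_stack([x, y]), kappa


def fit_folding_angle(
    points: np.ndarray,
    arm_length: float = 10.0,
    step: float = 0.25,
    smooth_um: float = 1.0,
    min_crease_curvature: float = 0.01,
) -> float:
    """Folding angle (degrees) of a surface profile at its crease.

    The crease is the concave-curvature maximum of the profile.  A straight
    line is fitted (total least squares) to each flank over ``arm_length``
    micrometres of arc starting just outside the rounded crease tip, and the
    angle between the two flank directions is returned: 180° for a flat
    profile, smaller for a deeper fold.

    Returns ``nan`` when the profile is too short to carry both arms.
    """
    rs, kappa = profile_curvature(points, step=step, smooth_um=smooth_um)
    n = len(rs)
    guard = max(3, int(round(arm_length / (2 * step))))
    if n < 2 * guard + 3:
        return float("nan")
    interior = kappa[guard : n - guard]
    if interior.size == 0 or np.nanmax(interior) < min_crease_curvature:
        return 180.0  # no crease: flat profile
    ic = guard + int(np.nanargmax(interior))
    # skip the blended tip: start the arms where curvature has fallen off
    tip = max(1, int(round(0.5 / step)))
    arm_n = max(3, int(round(arm_length / step)))
    left = rs[max(0, ic - tip - arm_n) : ic - tip + 1]
    right = rs[ic + tip : min(n, ic + tip + arm_n + 1)]
    if len(left) < 3 or len(right) < 3:
        return float("nan")

    def _direction(seg: np.ndarray, away_from: np.ndarray) -> np.ndarray:
        c = seg.mean(axis=0)
        u, s, vt = np.linalg.svd(seg - c)
        d = vt[0]
        if np.dot(d, c - away_from) < 0:
            d = -d
        return d

    crease = rs[ic]
    d1 = _direction(left, crease)
    d2 = _direction(right, crease)
    cosang = np.clip(np.dot(d1, d2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def polygon_area(outline: np.ndarray) -> float:
    """Planimetric area (shoelace) of a closed, simple 2D outline in μm².

    Raises ``ValueError`` for degenerate or self-intersecting outlines.
    """
    pts = np.asarray(outline, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("outline needs at least 3 distinct 2D points")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("outline needs at least 3 distinct 2D points")
    ring = LinearRing(pts)
    if not ring.is_valid or not ring.is_simple:
        raise ValueError("outline is self-intersecting")
    return float(Polygon(ring).area)
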