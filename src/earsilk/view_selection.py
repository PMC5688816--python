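"""Leaf-plane orientation and informative side-view selection.

Maize leaves lie essentially in one vertical plane.  A robust reduced major
axis (RMA) regression on the segmented top view recovers that plane's azimuth;
the side views whose camera azimuth is perpendicular to the plane see the stem
with least leaf occlusion.  A second RMA pass on the pixels rejected by the
first detects off-plane leaves that can still occlude a candidate view.

Conventions: image coordinates are (row down, col right); azimuths are
measured from the +col axis, counter-clockwise when the image is viewed
normally (i.e. with y = -row), in degrees.  A line direction is an azimuth
mod 180.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlaneOrientation:
    """RMA line through top-view plant pixels: leaf plane direction."""

    azimuth: float            # degrees in [0, 180)
    slope: float              # dy/dx in math coords (y = -row), inf for vertical
    intercept: float
    r_squared: float
    inlier_pixels: np.ndarray
    outlier_pixels: np.ndarray
    axes_swapped: bool = False
    anisotropy: float = 1.0   # 1 - eigenvalue ratio of the inlier cloud


@dataclass
class ViewSelection:
    selected_azimuths: tuple[int, ...]
    pass1: PlaneOrientation | None = None
    pass2: PlaneOrientation | None = None
    candidates: tuple[int, ...] = field(default_factory=tuple)
    fallback: bool = False


def _perp_residuals(x, y, slope, intercept):
    return np.abs(slope * x - y + intercept) / np.hypot(slope, 1.0)


def _rma_line(x, y):
    """Closed-form RMA: slope = sign(cov(x,y)) * sd(y)/sd(x)."""
    sx, sy = np.std(x), np.std(y)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    sign = 1.0 if cov >= 0 else -1.0
    slope = sign * sy / sx
    intercept = y.mean() - slope * x.mean()
    return slope, intercept


def rma_fit(points, robust_iters: int = 3, inlier_fraction: float = 0.9) -> PlaneOrientation:
    """Robust reduced major axis line through 2D points.

    Points are (x, y) with y up (callers converting from image coordinates
    should pass y = -row).  Robustness: after each fit, the (1 -
    inlier_fraction) points with largest perpendicular residual are discarded
    and the line refit, ``robust_iters`` times.  Near-vertical clouds
    (sd(x) << sd(y)) are fit with axes swapped; the reported slope/azimuth
    refer to the original axes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.std(x) == 0 and np.std(y) == 0:
        raise ValueError("all points identical; no line defined")
    swapped = np.std(x) < 0.25 * np.std(y)
    if swapped:
        x, y = y, x
    keep = np.ones(len(x), dtype=bool)
    for _ in range(max(1, robust_iters)):
        xi, yi = x[keep], y[keep]
        if np.std(xi) == 0:
            break
        slope, intercept = _rma_line(xi, yi)
        res = _perp_residuals(x, y, slope, intercept)
        # discard at most the (1 - inlier_fraction) worst points per pass,
        # and only those clearly off the line (> 2.5x the median residual):
        # a cloud that already fits well loses nothing
        med = np.median(res[keep])
        gate = max(2.5 * med, 1.5)
        n_keep = max(3, int(np.ceil(inlier_fraction * keep.sum())))
        order = np.argsort(res + np.where(keep, 0.0, np.inf))
        new_keep = np.zeros_like(keep)
        new_keep[order[:n_keep]] = True
        new_keep |= keep & (res <= gate)
        if np.array_equal(new_keep, keep):
            keep = new_keep
            break
        keep = new_keep
    xi, yi = x[keep], y[keep]
    slope, intercept = _rma_line(xi, yi)
    if np.std(xi) > 0 and np.std(yi) > 0:
        r2 = float(np.corrcoef(xi, yi)[0, 1] ** 2)
    else:
        r2 = 1.0
    if swapped:
        azimuth = np.degrees(np.arctan2(1.0, slope)) % 180.0
        slope_out = np.inf if slope == 0 else 1.0 / slope
        intercept_out = np.nan if slope == 0 else -intercept / slope
    else:
        azimuth = np.degrees(np.arctan(slope)) % 180.0
        slope_out, intercept_out = slope, intercept
    evals = np.linalg.eigvalsh(np.cov(pts[keep].T))
    aniso = 1.0 - float(evals.min() / evals.max()) if evals.max() > 0 else 0.0
    return PlaneOrientation(
        azimuth=float(azimuth), slope=float(slope_out), intercept=float(intercept_out),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        inlier_pixels=pts[keep], outlier_pixels=pts[~keep], axes_swapped=bool(swapped),
        anisotropy=aniso,
    )


def _ang_dist(a, b, period=360.0):
    d = np.abs((np.asarray(a) - np.asarray(b)) % period)
    return np.minimum(d, period - d)


def _line_dist(a, b):
    """Angular distance between a view azimuth and a line direction (mod 180)."""
    return _ang_dist(a, b, period=180.0)


def select_views(top_mask: np.ndarray, camera_azimuths=tuple(range(0, 360, 30)),
                 tol: float = 25.0, robust_iters: int = 3,
                 inlier_fraction: float = 0.9, max_views: int = 6,
                 min_pixels: int = 100, min_anisotropy: float = 0.5,
                 min_outlier_frac: float = 0.05) -> ViewSelection:
    """Two-pass RMA view selection from a segmented top view.

    Pass 1 fits the dominant leaf plane (direction theta1); side views whose
    camera azimuth lies within ``tol`` of theta1 +/- 90 deg see the stem
    unoccluded and become candidates.  Pass 2 refits the pass-1 outliers; a
    candidate view looking along that secondary leaf direction (within
    ``tol`` of theta2 mod 180) is occluded by those leaves and is discarded.
    The result is clipped to [1, max_views] views, keeping the candidates
    closest to the perpendicular of theta1; ties break toward the smaller
    azimuth.  If the pixel cloud has no dominant direction (covariance
    anisotropy below ``min_anisotropy``, e.g. an isotropic disc) all
    views are candidates before clipping.
    """
    rows, cols = np.nonzero(np.asarray(top_mask, dtype=bool))
    if len(rows) < min_pixels:
        raise ValueError("insufficient top-view signal")
    pts = np.stack([cols.astype(float), -rows.astype(float)], axis=1)
    pass1 = rma_fit(pts, robust_iters, inlier_fraction)
    theta1 = pass1.azimuth
    perp = ((theta1 + 90.0) % 180.0)
    cams = np.asarray(camera_azimuths, dtype=float)

    if pass1.anisotropy < min_anisotropy:
        candidates = list(cams)
        fallback = True
    else:
        candidates = [a for a in cams if _line_dist(a, perp) <= tol]
        fallback = False
        if not candidates:
            candidates = [min(cams, key=lambda a: (_line_dist(a, perp), a))]

    pass2 = None
    min_out = max(50, int(min_outlier_frac * len(pts)))
    if len(pass1.outlier_pixels) >= min_out and not fallback:
        try:
            pass2 = rma_fit(pass1.outlier_pixels, robust_iters, inlier_fraction)
        except ValueError:
            pass2 = None
        if pass2 is not None and pass2.anisotropy < min_anisotropy:
            pass2 = None  # rejected pixels have no coherent leaf direction
    if pass2 is not None:
        survivors = [a for a in candidates if _line_dist(a, pass2.azimuth) > tol]
        if survivors:
            candidates = survivors
        else:
            # every perpendicular view is occluded by the secondary leaf
            # group; fall back to the nearest unoccluded views instead
            unflagged = [a for a in cams if _line_dist(a, pass2.azimuth) > tol]
            if unflagged:
                candidates = unflagged

    candidates = sorted(candidates, key=lambda a: (_line_dist(a, perp), a))
    selected = tuple(int(a) for a in candidates[:max_views])
    if not selected:
        raise ValueError("no candidate views; degenerate top mask")
    return ViewSelection(selected_azimuths=selected, pass1=pass1, pass2=pass2,
                         candidates=tuple(int(a) for a in candidates), fallback=fallback)
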