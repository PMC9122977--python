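"""Cubic-spline smoothing and equal-arc-length bead resampling.

An ordered point path is smoothed by a cubic spline parameterized by
cumulative chord length, then resampled so that beads are evenly spaced in
arc length — each bead of the resulting model represents an equal fragment
of chromatin fiber.  With fewer than 4 distinct points the spline degenerates
to piecewise-linear interpolation.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def _dedupe_consecutive(points: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate points (zero chord steps break the spline)."""
    if len(points) < 2:
        return points
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 0
    return points[keep]


def spline_interpolate(ordered_points, n_beads: int, dense_factor: int = 10) -> np.ndarray:
    """Resample an ordered path into ``n_beads`` evenly spaced beads.

    Parameters
    ----------
    ordered_points : array-like, shape (m, 3)
        Path vertices in visiting order (nm).
    n_beads : int
        Number of output beads (>= 2).  First and last bead coincide with
        the curve endpoints.
    dense_factor : int
        Oversampling factor for the numerical arc-length inversion.

    Returns
    -------
    ndarray, shape (n_beads, 3)
    """
    pts = np.asarray(ordered_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (m, 3) point array, got shape {pts.shape}")
    if n_beads < 2:
        raise ValueError("n_beads must be >= 2")
    pts = _dedupe_consecutive(pts)
    m = len(pts)
    if m < 2:
        raise ValueError("need at least 2 distinct points to interpolate")

    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate(([0.0], np.cumsum(chord)))

    if m < 4:
        # piecewise-linear fallback: chord length equals arc length
        s_target = np.linspace(0.0, t[-1], n_beads)
        beads = np.column_stack([np.interp(s_target, t, pts[:, k]) for k in range(3)])
        beads[0], beads[-1] = pts[0], pts[-1]
        return beads

    spline = CubicSpline(t, pts, axis=0, bc_type="natural")
    n_dense = dense_factor * max(m, n_beads)
    t_dense = np.linspace(0.0, t[-1], n_dense)
    curve = spline(t_dense)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s_dense = np.concatenate(([0.0], np.cumsum(seg)))
    s_target = np.linspace(0.0, s_dense[-1], n_beads)
    t_target = np.interp(s_target, s_dense, t_dense)
    beads = spline(t_target)
    beads[0], beads[-1] = pts[0], pts[-1]
    return beads


def arc_length(points) -> float:
    """Polyline arc length of an ordered point path (nm)."""
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
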