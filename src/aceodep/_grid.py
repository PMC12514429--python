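"""Graded tensor-product grid shared by the potential and flow solvers.

The electric field has an integrable singularity at each electrode edge, so
the 1-D axes are refined geometrically toward those points (and toward both
electrode walls in y), from ``min_spacing`` at the feature up to
``target_spacing`` in the bulk.
"""

from __future__ import annotations

import numpy as np

from .core import ChamberGeometry2D, SolverSettings


def _one_sided(length: float, h_min: float, h_max: float, growth: float) -> np.ndarray:
    """Spacings summing exactly to ``length``, starting at ~h_min and growing
    geometrically to ~h_max, the remainder filled uniformly."""
    if length <= 0:
        return np.empty(0)
    if length <= 2 * h_min:
        return np.array([length])
    spac: list[float] = []
    h, total = h_min, 0.0
    while h < h_max and total + h < length:
        spac.append(h)
        total += h
        h *= growth
    rem = length - total
    if rem > 1e-30:
        k = max(1, int(round(rem / h_max)))
        spac.extend([rem / k] * k)
    return np.asarray(spac)


def _segment(length: float, h: float, h_min: float, growth: float,
             refine_start: bool, refine_end: bool) -> np.ndarray:
    """Interval spacings for one segment with optional end refinement."""
    if length <= 0:
        return np.empty(0)
    if not refine_start and not refine_end:
        k = max(2, int(np.ceil(length / h)))
        return np.full(k, length / k)
    if refine_start and refine_end:
        left = _one_sided(length / 2, h_min, h, growth)
        return np.concatenate([left, left[::-1]])
    spac = _one_sided(length, h_min, h, growth)
    return spac if refine_start else spac[::-1]


def build_grid(geometry: ChamberGeometry2D, settings: SolverSettings) -> tuple[np.ndarray, np.ndarray]:
    """Node coordinates (x, y) for the chamber cell, electrode edges on-node."""
    W, H = geometry.cell_width, geometry.height
    xl, xr = geometry.electrode_span
    h, hmin, g = settings.target_spacing, settings.min_spacing, settings.growth

    eps = 1e-12 * W
    breaks = [0.0]
    for b in (xl, xr, W):
        if b > breaks[-1] + eps:
            breaks.append(b)
    interior_refine = {xl, xr} - {0.0, W}
    spacings = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        spacings.append(
            _segment(b - a, h, hmin, g,
                     refine_start=any(abs(a - p) <= eps for p in interior_refine),
                     refine_end=any(abs(b - p) <= eps for p in interior_refine))
        )
    x = np.concatenate([[0.0], np.cumsum(np.concatenate(spacings))])
    x[-1] = W

    ys = _segment(H, h, hmin, g, refine_start=True, refine_end=True)
    y = np.concatenate([[0.0], np.cumsum(ys)])
    y[-1] = H
    return x, y


def electrode_mask(x: np.ndarray, geometry: ChamberGeometry2D) -> np.ndarray:
    """Boolean mask of x-nodes lying on the bottom electrode segment."""
    xl, xr = geometry.electrode_span
    tol = 1e-9 * max(geometry.cell_width, 1e-12)
    return (x >= xl - tol) & (x <= xr + tol)


def control_widths(coords: np.ndarray) -> np.ndarray:
    """Finite-volume control widths: half-cells at the two boundary nodes."""
    w = np.empty_like(coords)
    w[1:-1] = (coords[2:] - coords[:-2]) / 2.0
    w[0] = (coords[1] - coords[0]) / 2.0
    w[-1] = (coords[-1] - coords[-2]) / 2.0
    return w


def d2_coeffs(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-uniform 3-point second-derivative weights for interior nodes.

    Returns (a, b, c) such that f''(x_i) ~ a_i f_{i-1} + b_i f_i + c_i f_{i+1}
    for i = 1 .. n-2 (arrays of length n-2).
    """
    hm = np.diff(coords)[:-1]
    hp = np.diff(coords)[1:]
    a = 2.0 / (hm * (hm + hp))
    c = 2.0 / (hp * (hm + hp))
    b = -2.0 / (hm * hp)
    return a, b, c
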