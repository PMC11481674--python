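"""Ellipse geometry helpers shared by the simulator and the profiler.

Coordinates are 0-based pixel indices with pixel centers at integer
coordinates, row-major (row = y, column = x). Ellipse orientation is the
angle of the major axis from the +x (column) axis, in [0, pi). The
parametric start point t = 0 is the major-axis vertex; arc length grows
with t (counter-clockwise in (x, y) array coordinates).
"""

from __future__ import annotations

import numpy as np

N_DENSE = 4096


def ellipse_point(t: np.ndarray, cx: float, cy: float, a: float, b: float,
                  theta: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) pixel coordinates of ellipse points at parameter ``t``."""
    ct, st = np.cos(t), np.sin(t)
    co, so = np.cos(theta), np.sin(theta)
    x = cx + a * ct * co - b * st * so
    y = cy + a * ct * so + b * st * co
    return x, y


def arclength_table(a: float, b: float, n: int = N_DENSE
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Dense (t, cumulative arc length) table and the full perimeter.

    Arc length is in the same units as the semi-axes (pixels here).
    """
    t = np.linspace(0.0, 2 * np.pi, n + 1)
    # speed |dp/dt| = sqrt(a^2 sin^2 t + b^2 cos^2 t), rotation-invariant
    speed = np.sqrt(a**2 * np.sin(t) ** 2 + b**2 * np.cos(t) ** 2)
    ds = 0.5 * (speed[1:] + speed[:-1]) * np.diff(t)
    s = np.concatenate([[0.0], np.cumsum(ds)])
    return t, s, float(s[-1])


def arc_to_param(arc: np.ndarray, a: float, b: float) -> np.ndarray:
    """Invert arc length -> parameter t by interpolation on the dense table."""
    t, s, perim = arclength_table(a, b)
    return np.interp(np.asarray(arc) % perim, s, t)


def arc_to_point(arc: np.ndarray, cx: float, cy: float, a: float, b: float,
                 theta: float) -> tuple[np.ndarray, np.ndarray]:
    t = arc_to_param(arc, a, b)
    return ellipse_point(t, cx, cy, a, b, theta)


def outward_normal(t: np.ndarray, a: float, b: float, theta: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Unit outward normal (nx, ny) at parameter ``t``."""
    ct, st = np.cos(t), np.sin(t)
    co, so = np.cos(theta), np.sin(theta)
    # gradient of the implicit form in the cell frame is (cos t / a, sin t / b)
    gx_local = ct / a
    gy_local = st / b
    nx = gx_local * co - gy_local * so
    ny = gx_local * so + gy_local * co
    norm = np.hypot(nx, ny)
    return nx / norm, ny / norm


def circular_distance(p: np.ndarray, q: np.ndarray, period: float) -> np.ndarray:
    """Shortest distance between positions on a circle of circumference period."""
    d = np.abs(np.asarray(p) - np.asarray(q)) % period
    return np.minimum(d, period - d)


def rasterize_ellipse(shape: tuple[int, int], cx: float, cy: float, a: float,
                      b: float, theta: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the ellipse."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    dx = cols - cx
    dy = rows - cy
    co, so = np.cos(theta), np.sin(theta)
    u = dx * co + dy * so
    v = -dx * so + dy * co
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
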