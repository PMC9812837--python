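"""Planar geometry: Euclidean distances and the minimum enclosing circle.

Coordinates are planar (projected) and expressed in kilometres throughout.
The minimum enclosing circle is computed with the randomized incremental
(Welzl move-to-front) algorithm, which is exact for one- and two-point
inputs and runs in expected linear time. The permutation is drawn from a
fixed internal seed so results are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

#: absolute tolerance, km, for point-in-circle tests
MEC_TOL = 1e-9


@dataclass(frozen=True)
class Circle:
    """A circle in the plane; ``center_x``/``center_y``/``radius`` in km."""

    center_x: float
    center_y: float
    radius: float

    def contains(self, x, y, tol: float = MEC_TOL) -> np.ndarray:
        """Vectorized point-in-circle test (boundary counts as inside)."""
        d = np.hypot(np.asarray(x, float) - self.center_x,
                     np.asarray(y, float) - self.center_y)
        return d <= self.radius + tol


def distance_km(a, b) -> float:
    """Euclidean distance between two (x, y) points in km."""
    ax, ay = a
    bx, by = b
    return float(np.hypot(bx - ax, by - ay))


def _circle_two(p, q) -> Circle:
    cx = 0.5 * (p[0] + q[0])
    cy = 0.5 * (p[1] + q[1])
    return Circle(cx, cy, float(np.hypot(p[0] - cx, p[1] - cy)))


def _circumcircle(p, q, r) -> Circle | None:
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None  # collinear
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    c2 = cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    return Circle(ux, uy, float(np.hypot(ax - ux, ay - uy)))


def _in(c: Circle, p) -> bool:
    return np.hypot(p[0] - c.center_x, p[1] - c.center_y) <= c.radius + MEC_TOL


def _mec_two_fixed(pts, p, q) -> Circle:
    circ = _circle_two(p, q)
    for r in pts:
        if not _in(circ, r):
            cc = _circumcircle(p, q, r)
            if cc is not None:
                circ = cc
            else:
                # collinear triple: widest diameter pair wins
                circ = max(
                    (_circle_two(p, q), _circle_two(p, r), _circle_two(q, r)),
                    key=lambda c: c.radius,
                )
    return circ


def _mec_one_fixed(pts, p) -> Circle:
    circ = Circle(float(p[0]), float(p[1]), 0.0)
    for j, q in enumerate(pts):
        if not _in(circ, q):
            circ = _mec_two_fixed(pts[: j + 1], p, q)
    return circ


def minimum_enclosing_circle(points) -> Circle:
    """Smallest circle containing every point of ``points`` (n x 2 array-like).

    Exact for 1 and 2 points; for larger inputs all generating points lie
    within ``radius + 1e-9`` km of the centre.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise InsufficientDataError("minimum enclosing circle of an empty set")
    if pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y")
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return Circle(float(pts[0, 0]), float(pts[0, 1]), 0.0)
    rng = np.random.default_rng(182731)  # fixed: determinism, not statistics
    pts = pts[rng.permutation(len(pts))]
    circ = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if not _in(circ, pts[i]):
            circ = _mec_one_fixed(pts[:i], pts[i])
    return circ
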