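"""Small planar-geometry helpers shared across the pipeline.

Points are ``(row, col)`` pairs in pixel units. Angles with the
horizontal axis are measured counter-clockwise (row axis pointing up),
so a segment running along increasing columns has angle 0 and one along
increasing rows has angle -90 (axially, 90).
"""

from __future__ import annotations

import numpy as np

#: Full turn of axial data: orientations are identified modulo 180 deg.
AXIAL_PERIOD_DEG = 180.0


def axial_angle_deg(p, q) -> float:
    """Axial angle in [0, 180) of the segment p->q with the horizontal axis."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    drow, dcol = q[0] - p[0], q[1] - p[1]
    return float(np.degrees(np.arctan2(-drow, dcol)) % AXIAL_PERIOD_DEG)


def enclosed_angle_deg(a, v, b) -> float:
    """Interior angle at vertex v between rays v->a and v->b, in [0, 180].

    180 means a and b continue each other in a straight line through v;
    small values mean a sharp hairpin. This is the "enclosed angle" of a
    bend between two consecutive straight filament parts.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    b = np.asarray(b, dtype=float)
    u1 = a - v
    u2 = b - v
    n1 = np.hypot(*u1)
    n2 = np.hypot(*u2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate ray in enclosed angle")
    c = float(np.dot(u1, u2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (n, 2) array of points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least two points")
    return float(np.sum(np.hypot(*(np.diff(pts, axis=0).T))))


def point_segment_distance(points: np.ndarray, p, q) -> np.ndarray:
    """Euclidean distance from each row of `points` to segment [p, q]."""
    pts = np.asarray(points, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - p
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("degenerate segment")
    t = np.clip((pts - p) @ d / denom, 0.0, 1.0)
    proj = p + t[:, None] * d
    return np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1])
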