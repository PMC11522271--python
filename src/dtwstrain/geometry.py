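"""Small planar-geometry kernel shared across the pipeline.

Conventions (used everywhere in this package):

* points are ``(x, y)`` with ``x = column``, ``y = row``, origin at the
  top-left pixel corner, ``y`` increasing downward;
* polygons are ``(N, 2)`` arrays in traversal order, implicitly closed;
* areas are absolute shoelace areas in px².
"""

from __future__ import annotations

import numpy as np


def shoelace_area(polygon: np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon given as (N, 2) vertices."""
    p = np.asarray(polygon, dtype=float)
    if len(p) < 3:
        return 0.0
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polyline_length(points: np.ndarray) -> float:
    """Total Euclidean length of an open polyline."""
    p = np.asarray(points, dtype=float)
    if len(p) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(p, axis=0).T)))


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex; ``out[0] == 0``."""
    p = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(p, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, s_values: np.ndarray) -> np.ndarray:
    """Linearly interpolate a polyline at the given arc-length positions."""
    p = np.asarray(points, dtype=float)
    s = cumulative_arclength(p)
    s_values = np.clip(np.asarray(s_values, dtype=float), 0.0, s[-1])
    x = np.interp(s_values, s, p[:, 0])
    y = np.interp(s_values, s, p[:, 1])
    return np.column_stack([x, y])


def project_point_onto_polyline(point: np.ndarray, polyline: np.ndarray) -> tuple[float, np.ndarray]:
    """Nearest point on a polyline.

    Returns ``(s, q)``: the arc-length position of the projection and the
    projected coordinate. The projection is continuous (segment interior
    allowed), not snapped to a vertex.
    """
    p = np.asarray(point, dtype=float)
    poly = np.asarray(polyline, dtype=float)
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / seg_len2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", proj - p, proj - p)
    k = int(np.argmin(d2))
    s = cumulative_arclength(poly)
    s_hit = s[k] + t[k] * (s[k + 1] - s[k])
    return float(s_hit), proj[k]
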