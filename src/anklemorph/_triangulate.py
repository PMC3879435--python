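"""Minimal ear-clipping triangulation for simple polygons.

Used to cap the extruded phantom cross-sections; O(n^2) is plenty for the
few-hundred-vertex outlines produced there.
"""

from __future__ import annotations

import numpy as np


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _point_in_triangle(p, a, b, c, eps: float = 1e-12) -> bool:
    d1 = _cross(a, b, p)
    d2 = _cross(b, c, p)
    d3 = _cross(c, a, p)
    neg = (d1 < -eps) or (d2 < -eps) or (d3 < -eps)
    pos = (d1 > eps) or (d2 > eps) or (d3 > eps)
    return not (neg and pos)


def triangulate_polygon(points: np.ndarray) -> np.ndarray:
    """Triangulate a simple (non self-intersecting) polygon by ear clipping.

    Parameters
    ----------
    points : (N, 2) array of vertices in order (either orientation).

    Returns
    -------
    (M, 3) integer array of triangle indices into ``points`` with
    counter-clockwise winding in the input plane.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    # signed area -> enforce CCW index order
    x, y = pts[:, 0], pts[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    idx = list(range(n)) if area2 > 0 else list(range(n))[::-1]

    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 10 * n * n:
            raise ValueError("ear clipping failed: polygon may be self-intersecting")
        m = len(idx)
        clipped = False
        for i in range(m):
            i0, i1, i2 = idx[(i - 1) % m], idx[i], idx[(i + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            if _cross(a, b, c) <= 1e-12:  # reflex or degenerate corner
                continue
            others = [j for j in idx if j not in (i0, i1, i2)]
            if any(_point_in_triangle(pts[j], a, b, c) for j in others):
                continue
            tris.append((i0, i1, i2))
            idx.pop(i)
            clipped = True
            break
        if not clipped:
            # fall back: drop the most degenerate corner to make progress
            areas = []
            for i in range(m):
                i0, i1, i2 = idx[(i - 1) % m], idx[i], idx[(i + 1) % m]
                areas.append(abs(_cross(pts[i0], pts[i1], pts[i2])))
            i = int(np.argmin(areas))
            i0, i1, i2 = idx[(i - 1) % m], idx[i], idx[(i + 1) % m]
            tris.append((i0, i1, i2))
            idx.pop(i)
    tris.append((idx[0], idx[1], idx[2]))
    return np.asarray(tris, dtype=np.int64)
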