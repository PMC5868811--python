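"""Planar geometry helpers shared by the generator and the measurement code.

All polylines are ``(n, 2)`` float arrays in (row, col) pixel coordinates,
listed once (the closing edge back to the first vertex is implicit).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def closed_polyline_lengths(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-edge lengths of a closed polyline and its total perimeter."""
    pts = np.asarray(points, dtype=float)
    nxt = np.roll(pts, -1, axis=0)
    seg = np.hypot(*(nxt - pts).T)
    return seg, float(seg.sum())


def resample_closed(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Resample a closed polyline at a fixed arc-length step.

    Returns ``(samples, arc_positions, perimeter)`` where ``arc_positions``
    are the distances along the boundary of each sample in ``[0, perimeter)``.
    """
    pts = np.asarray(points, dtype=float)
    seg, total = closed_polyline_lengths(pts)
    if total <= 0:
        return pts[:1].copy(), np.zeros(1), 0.0
    # cumulative arc length at each vertex, with the first vertex repeated at
    # the end so np.interp can wrap around the closing edge
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    closed = np.vstack([pts, pts[:1]])
    t = np.arange(0.0, total, step)
    rows = np.interp(t, cum, closed[:, 0])
    cols = np.interp(t, cum, closed[:, 1])
    return np.column_stack([rows, cols]), t, total


def min_feret_diameter(points: np.ndarray) -> float:
    """Minimum caliper width of a point set (rotating calipers on the hull).

    For a convex polygon the minimum width is attained with one caliper jaw
    flush against a hull edge, so scanning hull edges is exact.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) == 2:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # collinear input: width zero
        return 0.0
    verts = pts[hull.vertices]
    nxt = np.roll(verts, -1, axis=0)
    edges = nxt - verts
    lengths = np.hypot(*edges.T)
    keep = lengths > 0
    edges, origins, lengths = edges[keep], verts[keep], lengths[keep]
    # unit normals of each edge
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lengths[:, None]
    # distance of every hull vertex from every edge line
    offsets = verts[None, :, :] - origins[:, None, :]
    dist = np.abs(np.einsum("eij,ej->ei", offsets, normals))
    widths = dist.max(axis=1)
    return float(widths.min())


def polygon_area(points: np.ndarray) -> float:
    """Shoelace area of a simple closed polygon."""
    pts = np.asarray(points, dtype=float)
    r, c = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def merge_circular_intervals(
    intervals: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Merge overlapping intervals on the unit circle.

    Intervals are (start, end) with 0 <= start < 1 and end > start (end may
    exceed 1, meaning the interval wraps). Returns disjoint intervals in the
    same convention, sorted by start.
    """
    if not intervals:
        return []
    # split wrapped intervals into linear pieces on [0, 1)
    pieces: list[tuple[float, float]] = []
    for a, b in intervals:
        a = a % 1.0
        length = min(b - a, 1.0)
        if length <= 0:
            continue
        if a + length <= 1.0:
            pieces.append((a, a + length))
        else:
            pieces.append((a, 1.0))
            pieces.append((0.0, a + length - 1.0))
    if not pieces:
        return []
    pieces.sort()
    merged = [list(pieces[0])]
    for a, b in pieces[1:]:
        if a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # rejoin across the 0/1 seam: represent the joined interval as wrapping
    # past 1.0, placed last so starts remain sorted
    if (
        len(merged) > 1
        and merged[0][0] <= 1e-12
        and merged[-1][1] >= 1.0 - 1e-12
    ):
        first = merged.pop(0)
        merged[-1][1] = first[1] + 1.0
    return [(a, min(b, a + 1.0)) for a, b in merged]


def total_interval_length(intervals: list[tuple[float, float]]) -> float:
    return float(sum(min(b - a, 1.0) for a, b in intervals))


def complement_circular_intervals(
    intervals: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Complement of disjoint sorted circular intervals on [0, 1)."""
    if not intervals:
        return [(0.0, 1.0)]
    if total_interval_length(intervals) >= 1.0 - 1e-9:
        return []
    out = []
    for (a0, b0), (a1, _) in zip(intervals, intervals[1:] + intervals[:1]):
        start = b0 % 1.0
        end = a1 if a1 > start else a1 + 1.0
        if end - start > 1e-12:
            out.append((start, end))
    return out
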