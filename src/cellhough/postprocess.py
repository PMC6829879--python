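"""Correction of unreasonable detections and assembly of per-cell polylines.

Raw Hough output suffers two systematic artifacts: one cell marked by
several near-parallel lines, and one slender cell fragmented into
several short segments.  Two rules fix them, applied in this order:

1. *Duplicate removal* — if two segments lie closer than 15 pixels with
   an included angle under 20 degrees, the shorter one is removed and
   the longer retained (both inequalities strict).
2. *Fragment merging* — segments that intersect, or whose endpoints lie
   within a small join tolerance, are integrated into one piecewise
   line (:class:`PolylineCell`) representing a single cell; its summed
   segment length is the reported cell length.

Segment geometry (minimum distance, intersection) is delegated to
shapely; "distance" means the minimal point-pair distance between the
two closed segments — infinite-line distance would be zero for any
non-parallel pair and make the rule vacuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import LineString, Point

from .hough import LineSegment

DEFAULT_DIST_THRESH = 15.0  # px, duplicate radius
DEFAULT_ANGLE_THRESH = 20.0  # degrees, duplicate angle
DEFAULT_JOIN_TOL = 5.0  # px, endpoint gap for merging


def _as_shapely(seg: LineSegment):
    if seg.start == seg.end:  # degenerate segment treated as a point
        return Point(seg.start)
    return LineString([seg.start, seg.end])


def segment_min_distance(a: LineSegment, b: LineSegment) -> float:
    """Minimal Euclidean distance between two closed segments (pixels).

    Symmetric and non-negative; zero iff the segments touch or cross.
    """
    return float(_as_shapely(a).distance(_as_shapely(b)))


def included_angle(a: LineSegment, b: LineSegment) -> float:
    """Acute angle between the undirected segment directions, in degrees.

    Directions 10 deg and 170 deg are 20 deg apart (wrap-around of the
    undirected convention).  Raises on zero-length segments.
    """
    ax, ay = a.direction
    bx, by = b.direction
    cosang = min(1.0, abs(ax * bx + ay * by))
    return math.degrees(math.acos(cosang))


def _conflicts(a: LineSegment, b: LineSegment,
               dist_thresh: float, angle_thresh: float) -> bool:
    return (segment_min_distance(a, b) < dist_thresh
            and included_angle(a, b) < angle_thresh)


def _sort_key(seg: LineSegment):
    # longest first; ties broken by (theta, rho, x1, y1) for determinism
    return (-seg.length, seg.theta, seg.rho, seg.start[0], seg.start[1])


def remove_duplicates(
    segs: list[LineSegment],
    dist_thresh: float = DEFAULT_DIST_THRESH,
    angle_thresh: float = DEFAULT_ANGLE_THRESH,
) -> list[LineSegment]:
    """Drop near-parallel duplicate markings of the same cell.

    Greedy by descending length: a segment is kept iff it conflicts
    (distance < ``dist_thresh`` AND angle < ``angle_thresh``, both
    strict) with no already-kept segment.  The survivors therefore
    contain the longest member of every conflict and no surviving pair
    violates the rule.  Order-independent given the deterministic
    tie-break; idempotent.
    """
    if dist_thresh <= 0 or angle_thresh <= 0:
        raise ValueError("thresholds must be positive")
    kept: list[LineSegment] = []
    for seg in sorted(segs, key=_sort_key):
        if all(not _conflicts(seg, k, dist_thresh, angle_thresh)
               for k in kept):
            kept.append(seg)
    return kept


@dataclass
class PolylineCell:
    """A merged piecewise line representing one slender cell."""

    segments: list[LineSegment]
    id: int = 0
    total_length: float = field(init=False)

    def __post_init__(self):
        if not self.segments:
            raise ValueError("a PolylineCell needs at least one segment")
        self.total_length = float(sum(s.length for s in self.segments))

    @property
    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Terminal (start, end) points of the piecewise line.

        The two member endpoints with the largest mutual separation are
        taken as terminals; the one with the smaller (y, then x) is the
        start.  Deterministic by construction.
        """
        pts = [p for s in self.segments for p in (s.start, s.end)]
        best = max(
            ((p, q) for i, p in enumerate(pts) for q in pts[i:]),
            key=lambda pq: math.dist(pq[0], pq[1]),
        )
        p, q = best
        if (p[1], p[0]) <= (q[1], q[0]):
            return p, q
        return q, p

    @property
    def midpoint(self) -> tuple[float, float]:
        p, q = self.endpoints
        return ((p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0)


def polyline_length(cell: PolylineCell) -> float:
    """Total length of a piecewise line: sum of member segment lengths."""
    return float(sum(s.length for s in cell.segments))


def merge_fragments(
    segs: list[LineSegment],
    join_tol: float = DEFAULT_JOIN_TOL,
) -> list[PolylineCell]:
    """Integrate touching or nearly-touching segments into piecewise lines.

    Connected components under the relation "segments intersect OR some
    endpoint pair lies within ``join_tol``" become single
    :class:`PolylineCell` objects; isolated segments become
    single-segment cells.  Input is expected to be deduplicated already.
    Total summed length is conserved and the cell count never exceeds
    the segment count.
    """
    n = len(segs)
    if n == 0:
        return []
    geoms = [_as_shapely(s) for s in segs]
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if geoms[i].intersects(geoms[j]) or _endpoint_gap(
                segs[i], segs[j]
            ) <= join_tol:
                rows.append(i)
                cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    cells: list[PolylineCell] = []
    for comp in range(n_comp):
        members = [segs[i] for i in np.nonzero(labels == comp)[0]]
        members = _order_chain(members)
        cells.append(PolylineCell(segments=members, id=len(cells)))
    # deterministic output order: by start point of the chain
    cells.sort(key=lambda c: (c.endpoints[0][1], c.endpoints[0][0]))
    for i, c in enumerate(cells):
        c.id = i
    return cells


def _endpoint_gap(a: LineSegment, b: LineSegment) -> float:
    return min(
        math.dist(p, q)
        for p in (a.start, a.end)
        for q in (b.start, b.end)
    )


def _order_chain(members: list[LineSegment]) -> list[LineSegment]:
    """Order component members along their principal direction."""
    if len(members) == 1:
        return members
    mids = np.array(
        [((s.start[0] + s.end[0]) / 2, (s.start[1] + s.end[1]) / 2)
         for s in members]
    )
    centered = mids - mids.mean(axis=0)
    # principal axis of the midpoints; falls back to x for coincident mids
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0] if np.linalg.norm(vt[0]) else np.array([1.0, 0.0])
    proj = centered @ axis
    order = np.lexsort((mids[:, 0], mids[:, 1], proj))
    return [members[i] for i in order]
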