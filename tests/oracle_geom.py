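"""Independent brute-force computational geometry for oracle tests.

Everything here is hand-coded from first principles (shoelace areas, ray-cast
point-in-polygon, ear-clipping triangulation, Sutherland-Hodgman clipping
against convex regions, parametric segment clipping) and never calls shapely,
so it can serve as an independent cross-check of the package's geometry and
indicator computations on rectilinear fixtures.
"""

from __future__ import annotations

import math
from typing import Sequence

Pt = tuple[float, float]
Ring = list[Pt]


def shoelace_area(ring: Sequence[Pt]) -> float:
    """Signed area of a closed or open coordinate ring."""
    pts = list(ring)
    if pts[0] == pts[-1]:
        pts = pts[:-1]
    s = 0.0
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return 0.5 * s


def polygon_area_with_holes(exterior: Sequence[Pt], holes: Sequence[Sequence[Pt]] = ()) -> float:
    return abs(shoelace_area(exterior)) - sum(abs(shoelace_area(h)) for h in holes)


def point_in_ring(p: Pt, ring: Sequence[Pt]) -> bool:
    """Ray-cast point-in-polygon (even-odd); boundary points unspecified."""
    x, y = p
    pts = list(ring)
    if pts[0] == pts[-1]:
        pts = pts[:-1]
    inside = False
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def point_in_polygon(p: Pt, exterior: Sequence[Pt], holes: Sequence[Sequence[Pt]] = ()) -> bool:
    if not point_in_ring(p, exterior):
        return False
    return not any(point_in_ring(p, h) for h in holes)


def point_to_rect_distance(p: Pt, rect: tuple[float, float, float, float]) -> float:
    """Distance from point to an axis-aligned rectangle (0 inside)."""
    x, y = p
    minx, miny, maxx, maxy = rect
    dx = max(minx - x, 0.0, x - maxx)
    dy = max(miny - y, 0.0, y - maxy)
    return math.hypot(dx, dy)


# ---------------------------------------------------------------------------
# triangulation + clipping


def _ccw(ring: Sequence[Pt]) -> Ring:
    pts = list(ring)
    if pts[0] == pts[-1]:
        pts = pts[:-1]
    if shoelace_area(pts) < 0:
        pts = pts[::-1]
    return pts


def ear_clip(ring: Sequence[Pt]) -> list[tuple[Pt, Pt, Pt]]:
    """Triangulate a simple polygon (no holes) by ear clipping."""
    pts = _ccw(ring)
    # drop exactly-duplicate consecutive vertices
    clean: Ring = []
    for p in pts:
        if not clean or (abs(p[0] - clean[-1][0]) > 1e-12 or abs(p[1] - clean[-1][1]) > 1e-12):
            clean.append(p)
    pts = clean
    tris: list[tuple[Pt, Pt, Pt]] = []
    guard = 0
    while len(pts) > 3 and guard < 100_000:
        guard += 1
        n = len(pts)
        ear_found = False
        for i in range(n):
            a, b, c = pts[i - 1], pts[i], pts[(i + 1) % n]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-12:  # reflex or collinear
                if abs(cross) <= 1e-12 and _between(a, b, c):
                    pts.pop(i)  # collinear vertex, drop
                    ear_found = True
                    break
                continue
            tri = (a, b, c)
            if any(
                _point_strictly_in_tri(q, tri)
                for j, q in enumerate(pts)
                if q not in (a, b, c)
            ):
                continue
            tris.append(tri)
            pts.pop(i)
            ear_found = True
            break
        if not ear_found:
            raise RuntimeError("ear clipping failed (degenerate polygon)")
    if len(pts) == 3:
        tris.append((pts[0], pts[1], pts[2]))
    return tris


def _between(a: Pt, b: Pt, c: Pt) -> bool:
    return (
        min(a[0], c[0]) - 1e-9 <= b[0] <= max(a[0], c[0]) + 1e-9
        and min(a[1], c[1]) - 1e-9 <= b[1] <= max(a[1], c[1]) + 1e-9
    )


def _point_strictly_in_tri(p: Pt, tri: tuple[Pt, Pt, Pt]) -> bool:
    (ax, ay), (bx, by), (cx, cy) = tri
    d1 = (p[0] - bx) * (ay - by) - (ax - bx) * (p[1] - by)
    d2 = (p[0] - cx) * (by - cy) - (bx - cx) * (p[1] - cy)
    d3 = (p[0] - ax) * (cy - ay) - (cx - ax) * (p[1] - ay)
    return (d1 > 1e-12 and d2 > 1e-12 and d3 > 1e-12) or (
        d1 < -1e-12 and d2 < -1e-12 and d3 < -1e-12
    )


def clip_convex(subject: Sequence[Pt], clipper: Sequence[Pt]) -> Ring:
    """Sutherland-Hodgman: clip a polygon by a convex CCW clip region."""
    out = list(subject)
    clip = _ccw(clipper)
    n = len(clip)
    for i in range(n):
        cp1, cp2 = clip[i], clip[(i + 1) % n]
        if not out:
            return []
        inp = out
        out = []

        def inside(p: Pt) -> bool:
            return (cp2[0] - cp1[0]) * (p[1] - cp1[1]) - (cp2[1] - cp1[1]) * (
                p[0] - cp1[0]
            ) >= -1e-12

        def intersect(s: Pt, e: Pt) -> Pt:
            dcx, dcy = cp1[0] - cp2[0], cp1[1] - cp2[1]
            dpx, dpy = s[0] - e[0], s[1] - e[1]
            n1 = cp1[0] * cp2[1] - cp1[1] * cp2[0]
            n2 = s[0] * e[1] - s[1] * e[0]
            den = dcx * dpy - dcy * dpx
            return ((n1 * dpx - n2 * dcx) / den, (n1 * dpy - n2 * dcy) / den)

        s = inp[-1]
        for e in inp:
            if inside(e):
                if not inside(s):
                    out.append(intersect(s, e))
                out.append(e)
            elif inside(s):
                out.append(intersect(s, e))
            s = e
    return out


def rect_ring(minx: float, miny: float, maxx: float, maxy: float) -> Ring:
    return [(minx, miny), (maxx, miny), (maxx, maxy), (minx, maxy)]


def area_polygon_rect(rings: Sequence[Ring], rect: tuple[float, float, float, float]) -> float:
    """Area of (possibly multi-part simple polygon) intersected with a rect,
    via triangulation + convex clipping."""
    clip = rect_ring(*rect)
    total = 0.0
    for ring in rings:
        for tri in ear_clip(ring):
            piece = clip_convex(list(tri), clip)
            if len(piece) >= 3:
                total += abs(shoelace_area(piece))
    return total


def area_polygon_polygon(rings_a: Sequence[Ring], rings_b: Sequence[Ring]) -> float:
    """Area of intersection of two (multi-part, hole-free) polygons via
    triangle-triangle Sutherland-Hodgman sums."""
    tris_a = [tri for ring in rings_a for tri in ear_clip(ring)]
    tris_b = [tri for ring in rings_b for tri in ear_clip(ring)]
    total = 0.0
    for ta in tris_a:
        for tb in tris_b:
            piece = clip_convex(list(ta), _ccw(list(tb)))
            if len(piece) >= 3:
                total += abs(shoelace_area(piece))
    return total


def rect_overlap_area(a: tuple, b: tuple) -> float:
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return max(w, 0.0) * max(h, 0.0)


def shared_edge_length(a: tuple, b: tuple) -> float:
    """Shared boundary length of two non-overlapping axis-aligned rects."""
    minxa, minya, maxxa, maxya = a
    minxb, minyb, maxxb, maxyb = b
    # vertical contact
    if abs(maxxa - minxb) < 1e-9 or abs(maxxb - minxa) < 1e-9:
        return max(0.0, min(maxya, maxyb) - max(minya, minyb))
    # horizontal contact
    if abs(maxya - minyb) < 1e-9 or abs(maxyb - minya) < 1e-9:
        return max(0.0, min(maxxa, maxxb) - max(minxa, minxb))
    return 0.0


def segment_length_in_polygon(
    p0: Pt, p1: Pt, rings: Sequence[Ring]
) -> float:
    """Length of the part of segment p0-p1 inside a (multi-part) polygon.

    Parametric clipping: intersect with every polygon edge, sort the
    parameters, classify each sub-interval by its midpoint.
    """
    ts = [0.0, 1.0]
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    for ring in rings:
        pts = _ccw(ring)
        n = len(pts)
        for i in range(n):
            a, b = pts[i], pts[(i + 1) % n]
            ex, ey = b[0] - a[0], b[1] - a[1]
            den = dx * ey - dy * ex
            if abs(den) < 1e-15:
                continue
            t = ((a[0] - p0[0]) * ey - (a[1] - p0[1]) * ex) / den
            u = ((a[0] - p0[0]) * dy - (a[1] - p0[1]) * dx) / den
            if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
                ts.append(min(max(t, 0.0), 1.0))
    ts = sorted(set(ts))
    seg_len = math.hypot(dx, dy)
    total = 0.0
    for t0, t1 in zip(ts[:-1], ts[1:]):
        tm = (t0 + t1) / 2.0
        mid = (p0[0] + tm * dx, p0[1] + tm * dy)
        if any(point_in_ring(mid, ring) for ring in rings):
            total += (t1 - t0) * seg_len
    return total


def zscore(values: Sequence[float]) -> list[float]:
    """Population z-scores, NaN-preserving, via the statistics formulae."""
    ok = [v for v in values if not math.isnan(v)]
    mean = sum(ok) / len(ok)
    sd = math.sqrt(sum((v - mean) ** 2 for v in ok) / len(ok))
    out = []
    for v in values:
        if math.isnan(v):
            out.append(float("nan"))
        elif sd == 0:
            out.append(0.0)
        else:
            out.append((v - mean) / sd)
    return out
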