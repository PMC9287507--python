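"""Planar geometry primitives shared by all indicators.

All coordinates are planar metres in an (assumed) projected CRS; no geodesy
anywhere. Geometries are shapely 2.x objects. The light dataclasses below carry
the thematic attributes (land-cover class, road id, visitor source) that plain
shapely geometries cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

#: Closed vocabulary of land-cover classes in a patch mosaic.
LANDCOVER_CLASSES = (
    "cropland",
    "semi_natural_grassland",
    "forest",
    "water",
    "built_up",
    "other_open",
)

#: Visitor point sources.
USER_SOURCES = ("photo", "species_observation")


class InvalidGeometryError(ValueError):
    """Raised for degenerate or self-intersecting input geometry."""


class InvalidMosaicError(ValueError):
    """Raised when patches of a mosaic overlap with positive area."""


class ParameterError(ValueError):
    """Raised for out-of-range numeric parameters."""


@dataclass(frozen=True)
class LandCoverPatch:
    """A classed polygon in a non-overlapping land-cover mosaic."""

    geometry: Polygon
    patch_class: str
    patch_id: str

    def __post_init__(self) -> None:
        if self.patch_class not in LANDCOVER_CLASSES:
            raise ValueError(
                f"unknown land-cover class {self.patch_class!r}; "
                f"expected one of {LANDCOVER_CLASSES}"
            )


@dataclass(frozen=True)
class RoadLine:
    """A road centre-line polyline."""

    geometry: LineString
    road_id: str

    def __post_init__(self) -> None:
        if len(self.geometry.coords) < 2 or not math.isfinite(self.geometry.length):
            raise InvalidGeometryError("road polyline needs >= 2 vertices, finite length")


@dataclass(frozen=True)
class UserPoint:
    """A georeferenced visitor record (photo upload or species observation)."""

    location: Point
    user_id: str
    source: str

    def __post_init__(self) -> None:
        if self.source not in USER_SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected {USER_SOURCES}")


def validate_polygon(poly: Polygon) -> Polygon:
    """Check ring closure, simplicity and positive area; return the polygon."""
    if not isinstance(poly, (Polygon, MultiPolygon)):
        raise InvalidGeometryError(f"expected polygon, got {type(poly).__name__}")
    if poly.is_empty or not poly.is_valid or poly.area <= 0:
        raise InvalidGeometryError("degenerate or self-intersecting polygon")
    return poly


def polygon_area(poly: Polygon) -> float:
    """Area in m2 (exterior minus holes)."""
    validate_polygon(poly)
    return float(poly.area)


def quad_segs_for_tolerance(distance: float, arc_tolerance: float | None) -> int:
    """Segments per quarter circle so the chord error stays below *arc_tolerance*.

    With no tolerance given, arcs are split into segments subtending <= 10
    degrees (9 per quarter), the package default.
    """
    if arc_tolerance is None:
        return 9
    if arc_tolerance <= 0:
        raise ParameterError("arc_tolerance must be positive")
    # chord sagitta e = r * (1 - cos(theta / 2))  ->  theta
    ratio = max(1.0 - arc_tolerance / distance, -1.0)
    theta = 2.0 * math.acos(ratio)
    if theta <= 0:
        return 64
    return max(1, math.ceil((math.pi / 2.0) / theta))


def buffer_region(
    geoms: Iterable[Polygon | LineString],
    distance: float,
    arc_tolerance: float | None = None,
) -> MultiPolygon | Polygon:
    """Merged union of round-capped dilations of *geoms* by *distance* metres."""
    if distance <= 0:
        raise ParameterError("buffer distance must be positive")
    geoms = list(geoms)
    if not geoms:
        raise ParameterError("no geometries to buffer")
    qs = quad_segs_for_tolerance(distance, arc_tolerance)
    return unary_union([g.buffer(distance, quad_segs=qs) for g in geoms])


def _check_mosaic(patches: Sequence[LandCoverPatch]) -> None:
    geoms = [p.geometry for p in patches]
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    for i, j in zip(left, right):
        if i >= j:
            continue
        inter = geoms[i].intersection(geoms[j])
        if inter.area > 1e-6:
            raise InvalidMosaicError(
                f"patches {patches[i].patch_id} and {patches[j].patch_id} overlap"
            )


def different_class_borders(
    patches: Sequence[LandCoverPatch], validate: bool = True
) -> list[shapely.Geometry]:
    """Line geometries shared by two patches of *different* class, each once.

    The outer mosaic boundary belongs to a single patch and never appears;
    edges between same-class patches are skipped.
    """
    if validate:
        _check_mosaic(patches)
    geoms = [p.geometry for p in patches]
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    borders: list[shapely.Geometry] = []
    for i, j in zip(left, right):
        if i >= j or patches[i].patch_class == patches[j].patch_class:
            continue
        shared = geoms[i].boundary.intersection(geoms[j].boundary)
        if shared.is_empty or shared.length == 0:
            continue
        borders.append(shared)
    return borders


def shared_border_length(
    patches: Sequence[LandCoverPatch],
    window: Polygon | MultiPolygon | None = None,
    validate: bool = True,
    borders: Sequence[shapely.Geometry] | None = None,
) -> float:
    """Total length (m) of different-class patch borders, clipped to *window*.

    Precomputed *borders* (from :func:`different_class_borders`) may be passed
    when the same mosaic is clipped against many windows.
    """
    if borders is None:
        borders = different_class_borders(patches, validate=validate)
    if not borders:
        return 0.0
    if window is None:
        return float(sum(b.length for b in borders))
    tree = STRtree(list(borders))
    idx = tree.query(window, predicate="intersects")
    total = 0.0
    for i in idx:
        total += borders[i].intersection(window).length
    return float(total)


def interior_grid(target: Polygon | MultiPolygon, spacing: float) -> np.ndarray:
    """Regular square grid of pitch *spacing* over *target*, offset half a pitch
    from the bounding-box corner; returns the (n, 2) points covered by target."""
    if spacing <= 0:
        raise ParameterError("grid spacing must be positive")
    minx, miny, maxx, maxy = target.bounds
    xs = np.arange(minx + spacing / 2.0, maxx, spacing)
    ys = np.arange(miny + spacing / 2.0, maxy, spacing)
    if xs.size == 0 or ys.size == 0:
        return np.empty((0, 2))
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = shapely.covers(target, shapely.points(pts))
    return pts[mask]


def mean_interior_distance(
    target: Polygon | MultiPolygon,
    habitats: Sequence[LandCoverPatch],
    excluded_classes: Iterable[str] = (),
    spacing: float = 25.0,
) -> float:
    """Mean distance from a grid of interior points to the nearest eligible
    (non-cropland, non-excluded) habitat patch.

    Returns NaN when no grid point falls inside the target or no eligible
    habitat exists anywhere.
    """
    excluded = set(excluded_classes) | {"cropland"}
    eligible = [p.geometry for p in habitats if p.patch_class not in excluded]
    if not eligible:
        return float("nan")
    pts = interior_grid(target, spacing)
    if pts.shape[0] == 0:
        return float("nan")
    tree = STRtree(eligible)
    _, dist = tree.query_nearest(
        shapely.points(pts), return_distance=True, all_matches=False
    )
    return float(np.mean(dist))


def overlay_area(
    a: Polygon | MultiPolygon | Iterable[Polygon],
    b: Polygon | MultiPolygon | Iterable[Polygon],
) -> float:
    """Area (m2) of the geometric intersection of two polygon sets."""
    ga = a if isinstance(a, (Polygon, MultiPolygon)) else unary_union(list(a))
    gb = b if isinstance(b, (Polygon, MultiPolygon)) else unary_union(list(b))
    if ga.is_empty or gb.is_empty:
        return 0.0
    return float(ga.intersection(gb).area)
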