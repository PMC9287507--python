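"""Independent brute-force recomputation of the nine indicators on the
rectilinear tile-world fixture.

Consumes only raw fixture data (tile rectangles, raw road endpoints,
axis-aligned protected/inventory rectangles, point coordinates) plus the
study-area polygon coordinates, and recomputes every indicator with the
hand-coded geometry in `oracle_geom` — no shapely anywhere.
"""

from __future__ import annotations

import math

import numpy as np

from oracle_geom import (
    area_polygon_rect,
    clip_convex,
    ear_clip,
    point_in_ring,
    point_to_rect_distance,
    polygon_area_with_holes,
    rect_overlap_area,
    segment_length_in_polygon,
    shoelace_area,
)

TILE = 500.0


def study_rings(study) -> list[list[tuple[float, float]]]:
    geom = study.polygons
    parts = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
    rings = []
    for p in parts:
        assert len(p.interiors) == 0, "fixture study areas must be hole-free"
        rings.append([(float(x), float(y)) for x, y in p.exterior.coords])
    return rings


def _road_quad(a, b, halfwidth: float):
    dx, dy = b[0] - a[0], b[1] - a[1]
    length = math.hypot(dx, dy)
    nx, ny = -dy / length * halfwidth, dx / length * halfwidth
    return [
        (a[0] + nx, a[1] + ny),
        (b[0] + nx, b[1] + ny),
        (b[0] - nx, b[1] - ny),
        (a[0] - nx, a[1] - ny),
    ]


def _union_area_in_tris(tris, convex_regions) -> float:
    """Area of (union of convex regions) within the triangles, by
    inclusion-exclusion over up to three regions."""
    total = 0.0
    k = len(convex_regions)
    import itertools

    for r in range(1, k + 1):
        sign = (-1) ** (r + 1)
        for combo in itertools.combinations(range(k), r):
            for tri in tris:
                piece = list(tri)
                for ci in combo:
                    piece = clip_convex(piece, convex_regions[ci])
                    if len(piece) < 3:
                        piece = []
                        break
                if len(piece) >= 3:
                    total += sign * abs(shoelace_area(piece))
    return total


def oracle_crpseq_parcel(seq, crop_cfg) -> float:
    years = len(seq)
    pair = sum(
        crop_cfg.succession.get((seq[t - 1], seq[t]), crop_cfg.succession_default)
        for t in range(1, years)
    ) / (years - 1)
    compliant = 0
    for t in range(1, years):
        prev = [u for u in range(t) if seq[u] == seq[t]]
        rt = crop_cfg.return_times.get(seq[t], 0)
        if not prev or t - prev[-1] >= rt:
            compliant += 1
    ret = compliant / (years - 1)
    div = (len(set(seq)) - 1) / (years - 1)
    return (
        crop_cfg.w_pair * pair + crop_cfg.w_return * ret + crop_cfg.w_div * div
    )


def oracle_raw_matrix(world) -> dict[str, dict[str, float]]:
    """farm_id -> {indicator/component -> value}, all hand-computed."""
    cfg = world.cfg
    # tile adjacency borders between different classes
    tile_of = {}
    for p in world.patches:
        minx, miny, *_ = p.geometry.bounds
        tile_of[(int(minx // TILE), int(miny // TILE))] = p.patch_class
    borders = []
    n = int(5000.0 // TILE)
    for i in range(n):
        for j in range(n):
            cls = tile_of[(i, j)]
            if i + 1 < n and tile_of[(i + 1, j)] != cls:
                x = (i + 1) * TILE
                borders.append(((x, j * TILE), (x, (j + 1) * TILE)))
            if j + 1 < n and tile_of[(i, j + 1)] != cls:
                y = (j + 1) * TILE
                borders.append(((i * TILE, y), ((i + 1) * TILE, y)))

    eligible_rects = [
        p.geometry.bounds
        for p in world.patches
        if p.patch_class not in ("cropland", "water", "built_up")
    ]
    all_tiles = {p.patch_id: p for p in world.patches}
    road_quads_100 = [_road_quad(a, b, 100.0) for a, b in world.road_segments]
    road_quads_adj = [
        _road_quad(a, b, cfg.rodvar_adjacency_m) for a, b in world.road_segments
    ]

    out: dict[str, dict[str, float]] = {}
    for farm in world.farms:
        study = world.study_areas[farm.farm_id]
        rings = study_rings(study)
        tris = [tri for ring in rings for tri in ear_clip(ring)]
        study_m2 = sum(polygon_area_with_holes(r) for r in rings)
        study_ha = study_m2 / 1e4
        row: dict[str, float] = {}

        # LanVar
        row["LanVar"] = (
            sum(segment_length_in_polygon(a, b, rings) for a, b in borders)
            / study_ha
        )

        # CrpDst
        crop_rects = [p.geometry.bounds for p in farm.cropland_parcels]
        minx = min(r[0] for r in crop_rects)
        miny = min(r[1] for r in crop_rects)
        maxx = max(r[2] for r in crop_rects)
        maxy = max(r[3] for r in crop_rects)
        sp = cfg.crpdst_spacing_m
        dists = []
        for x in np.arange(minx + sp / 2, maxx, sp):
            for y in np.arange(miny + sp / 2, maxy, sp):
                if any(
                    r[0] <= x <= r[2] and r[1] <= y <= r[3] for r in crop_rects
                ):
                    dists.append(
                        min(
                            point_to_rect_distance((x, y), r)
                            for r in eligible_rects
                        )
                    )
        row["CrpDst"] = float(np.mean(dists)) if dists else float("nan")

        # Gra
        agri_ha = farm.agricultural_area_ha
        grass_rects = [p.geometry.bounds for p in farm.grassland_parcels]
        G = sum((r[2] - r[0]) * (r[3] - r[1]) for r in grass_rects) / 1e4
        O = (
            sum(
                rect_overlap_area(g, inv)
                for g in grass_rects
                for inv in world.inventory_rects
            )
            / 1e4
        )
        row["Gra"] = (G + O) / agri_ha

        # SSHab
        crop_ha = farm.cropland_area_ha
        count = sum(
            1
            for h in world.habitats
            if any(
                r[0] <= h.location.x <= r[2] and r[1] <= h.location.y <= r[3]
                for r in crop_rects
            )
        )
        row["SSHab"] = count / crop_ha

        # CrpSeq (all fixture sequences complete)
        scores, areas = [], []
        for p in farm.cropland_parcels:
            scores.append(oracle_crpseq_parcel(list(p.crop_sequence), cfg.crop_config))
            areas.append(p.area_ha)
        row["CrpSeq"] = float(np.average(scores, weights=areas))

        # RodVar: distinct patches whose study-clipped part meets a road zone
        count = 0
        for patch in all_tiles.values():
            rect = patch.geometry.bounds
            inside = area_polygon_rect(rings, rect)
            if inside < 1e-6:
                continue
            touched = False
            for quad in road_quads_adj:
                for tri in tris:
                    piece = clip_convex(list(tri), [
                        (rect[0], rect[1]), (rect[2], rect[1]),
                        (rect[2], rect[3]), (rect[0], rect[3]),
                    ])
                    if len(piece) >= 3:
                        piece2 = clip_convex(piece, quad)
                        if len(piece2) >= 3 and abs(shoelace_area(piece2)) > 1e-9:
                            touched = True
                            break
                if touched:
                    break
            if touched:
                count += 1
        row["RodVar"] = count / study_ha

        # Acc components
        row["road_share"] = _union_area_in_tris(tris, road_quads_100) / study_m2
        row["pop_density"] = float(np.mean(world.pop_values))  # equal full cells

        # Visit components
        km2 = study_m2 / 1e6
        photo, obs = set(), set()
        for up in world.visitor_points:
            p = (up.location.x, up.location.y)
            if any(point_in_ring(p, ring) for ring in rings):
                (photo if up.source == "photo" else obs).add(up.user_id)
        row["photo_users_per_km2"] = len(photo) / km2
        row["obs_users_per_km2"] = len(obs) / km2

        # NatRes: per-layer union overlap, layers add
        total = 0.0
        for layer, rects in world.protected.items():
            regions = [
                [(r[0], r[1]), (r[2], r[1]), (r[2], r[3]), (r[0], r[3])]
                for r in rects
            ]
            total += _union_area_in_tris(tris, regions)
        row["NatRes"] = total / study_m2

        out[farm.farm_id] = row
    return out
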