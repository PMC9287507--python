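"""Shared fixtures.

`tile_world` is a fully rectilinear 10-farm landscape on a 5 km x 5 km world
partitioned into 500 m tiles: parcels occupy whole tiles, the matrix is made
of whole tiles, roads are straight lines spanning the world, and protected /
inventory layers are axis-aligned rectangles. Every geometric quantity in it
can therefore be recomputed from first principles by the hand-coded oracle in
`oracle_geom.py`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from farmscape.config import DEFAULT_CROPS, AnalysisConfig
from farmscape.geometry import LandCoverPatch, RoadLine, UserPoint
from farmscape.indicators import SmallScaleHabitat
from farmscape.registry import Parcel, build_farms, build_study_area

TILE = 500.0
WORLD = 5000.0


@dataclass
class TileWorld:
    farms: list
    study_areas: dict
    patches: list
    roads: list
    road_segments: list  # ((x0,y0),(x1,y1)) raw endpoints
    pop_cells: list
    pop_values: list
    visitor_points: list
    protected: dict  # layer -> list of (minx,miny,maxx,maxy)
    protected_unions: dict
    inventory_rects: list
    inventory_union: object
    habitats: list
    cfg: AnalysisConfig
    tile_of: dict = field(default_factory=dict)  # (i,j) -> (class, patch_id)


def _build_tile_world() -> TileWorld:
    rng = np.random.default_rng(42)
    n = int(WORLD // TILE)
    tiles = [(i, j) for i in range(n) for j in range(n)]
    order = rng.permutation(len(tiles))
    cursor = 0

    parcels: list[Parcel] = []
    records = []
    crops = [c for c in DEFAULT_CROPS]
    for k in range(10):
        farm_id = f"f{k:02d}"
        n_tiles = int(rng.integers(1, 4))
        livestock = {}
        farm_tiles = []
        for t in range(n_tiles):
            i, j = tiles[order[cursor]]
            cursor += 1
            land_use = (
                "semi_natural_grassland"
                if (t > 0 and rng.random() < 0.35)
                else "cropland"
            )
            seq = None
            if land_use == "cropland":
                seq = tuple(crops[int(c)] for c in rng.integers(0, len(crops), 7))
            geom = box(i * TILE, j * TILE, (i + 1) * TILE, (j + 1) * TILE)
            parcels.append(Parcel(f"p{k:02d}{t}", farm_id, geom, land_use, seq))
            farm_tiles.append((i, j, land_use))
        if any(lu == "semi_natural_grassland" for *_ij, lu in farm_tiles):
            livestock = {"sheep": 30}
        records.append(
            {"farm_id": farm_id, "hours": {"crops": 1000.0}, "counts": livestock}
        )

    matrix_classes = ["forest", "other_open", "water", "built_up"]
    patches = []
    tile_of = {}
    parcel_tiles = {
        (int(p.geometry.bounds[0] // TILE), int(p.geometry.bounds[1] // TILE)): p
        for p in parcels
    }
    for idx, (i, j) in enumerate(tiles):
        if (i, j) in parcel_tiles:
            p = parcel_tiles[(i, j)]
            cls = "cropland" if p.land_use == "cropland" else "semi_natural_grassland"
            patches.append(LandCoverPatch(p.geometry, cls, p.parcel_id))
            tile_of[(i, j)] = (cls, p.parcel_id)
        else:
            cls = matrix_classes[int(rng.integers(0, 4))]
            geom = box(i * TILE, j * TILE, (i + 1) * TILE, (j + 1) * TILE)
            pid = f"m{idx:03d}"
            patches.append(LandCoverPatch(geom, cls, pid))
            tile_of[(i, j)] = (cls, pid)

    segments = [
        ((-300.0, 1250.3), (WORLD + 300.0, 1250.3)),
        ((3750.7, -300.0), (3750.7, WORLD + 300.0)),
        ((-300.0, 4631.9), (WORLD + 300.0, 3110.2)),
    ]
    roads = [
        RoadLine(LineString([a, b]), f"r{i}") for i, (a, b) in enumerate(segments)
    ]

    pop_cells, pop_values = [], []
    for i in range(5):
        for j in range(5):
            pop_cells.append(
                box(i * 1000.0, j * 1000.0, (i + 1) * 1000.0, (j + 1) * 1000.0)
            )
            pop_values.append(float(np.round(rng.uniform(10, 500), 3)))

    visitor_points = []
    for s, source, n_pts, n_users in [(0, "photo", 30, 12), (1, "species_observation", 30, 10)]:
        xy = rng.uniform(0, WORLD, size=(n_pts, 2))
        users = rng.integers(0, n_users, size=n_pts)
        for k in range(n_pts):
            visitor_points.append(
                UserPoint(Point(xy[k]), f"u{s}{users[k]:03d}", source)
            )

    protected = {}
    for layer, count in [("nature_reserve", 2), ("natura2000", 3), ("national_interest", 3)]:
        rects = []
        for _ in range(count):
            cx, cy = rng.uniform(500, WORLD - 500, size=2)
            w, h = rng.uniform(400, 1800, size=2)
            rects.append((cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))
        protected[layer] = rects
    protected_unions = {
        layer: unary_union([box(*r) for r in rects])
        for layer, rects in protected.items()
    }

    inventory_rects = []
    for p in parcels:
        if p.land_use == "semi_natural_grassland" and rng.random() < 0.6:
            minx, miny, maxx, maxy = p.geometry.bounds
            inventory_rects.append((minx, miny, minx + (maxx - minx) / 2, maxy))
    inventory_union = (
        unary_union([box(*r) for r in inventory_rects])
        if inventory_rects
        else unary_union([])
    )

    habitats = []
    for p in parcels:
        if p.land_use != "cropland":
            continue
        minx, miny, maxx, maxy = p.geometry.bounds
        for _ in range(3):
            habitats.append(
                SmallScaleHabitat(
                    Point(
                        float(rng.uniform(minx + 1, maxx - 1)),
                        float(rng.uniform(miny + 1, maxy - 1)),
                    ),
                    "field_islet",
                )
            )
    # a few habitat points outside any cropland
    for _ in range(5):
        habitats.append(
            SmallScaleHabitat(
                Point(float(rng.uniform(0, WORLD)), float(rng.uniform(0, WORLD))),
                "clearance_cairn",
            )
        )

    cfg = AnalysisConfig()
    farms = build_farms(records, parcels, cfg)
    study_areas = {
        f.farm_id: build_study_area(f, cfg.study_buffer_m, cfg.arc_tolerance_m)
        for f in farms
    }
    return TileWorld(
        farms=farms,
        study_areas=study_areas,
        patches=patches,
        roads=roads,
        road_segments=segments,
        pop_cells=pop_cells,
        pop_values=pop_values,
        visitor_points=visitor_points,
        protected=protected,
        protected_unions=protected_unions,
        inventory_rects=inventory_rects,
        inventory_union=inventory_union,
        habitats=habitats,
        cfg=cfg,
    )


@pytest.fixture(scope="session")
def tile_world() -> TileWorld:
    return _build_tile_world()


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete simulated bundle shared across tests."""
    import farmscape as fs

    return fs.simulate(fs.SimulationConfig(n_farms=60, extent_m=25_000.0, seed=7))
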