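"""Synthetic landscape and farm-register generator.

Emulates, on a planar square world, the data sources the assessment consumes:
a farm register with enterprise hours and livestock head counts; agricultural
parcels (axis-aligned rectangles jittered on a coarse lattice) with per-year
crop codes over seven years; a land-cover mosaic whose non-farm matrix is a
Voronoi partition of random seed points; road polylines; a coarse population
raster with a radial urban gradient; georeferenced visitor points with user
identifiers from two sources; three protected-area layers; a semi-natural-
grassland quality inventory; and small-scale habitat points within cropland.

Ruminant-type farms receive higher ley shares and more grassland parcels, and
monogastric farms larger parcels, so the qualitative contrasts the analysis
targets exist by construction. A `homogeneous` configuration draws every
farm-level variable from the same distributions regardless of type, which
makes all downstream cluster comparisons null — the basis for type-I error
testing. Planted group effects shift a single indicator for a single farm
group by a chosen number of residual standard deviations for parameter-
recovery testing.

All randomness flows from one seed through named sub-streams, so identical
seeds give byte-identical bundles.
"""

from __future__ import annotations

import copy
import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import (
    LineString,
    MultiPoint,
    MultiPolygon,
    Point,
    Polygon,
    box,
)
from shapely.ops import unary_union, voronoi_diagram
from shapely.strtree import STRtree

from .config import DEFAULT_CROPS, INDICATORS, AnalysisConfig
from .geometry import LandCoverPatch, RoadLine, UserPoint
from .indicators import SmallScaleHabitat
from .io import read_feature_collection, write_feature_collection
from .registry import Farm, Parcel, build_farms


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named deterministic sub-stream of the global seed."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF]
    )


class SimulationConfigError(ValueError):
    pass


@dataclass
class FarmTypeParams:
    """Generative parameters for one detailed farm type."""

    proportion: float
    parcel_count: tuple[int, int] = (2, 5)  # uniform inclusive
    parcel_area_ha: tuple[float, float] = (4.0, 0.5)  # lognormal median, sigma
    grassland_parcel_prob: float = 0.2
    ley_affinity: float = 0.4  # 0..1, drives the crop Markov chain toward ley
    #: (probability, [(species, head_per_ha median, lognormal sigma), ...]);
    #: one option is drawn per farm, remaining probability means no livestock.
    livestock_options: list[tuple[float, list[tuple[str, float, float]]]] = field(
        default_factory=list
    )


def _default_types() -> dict[str, FarmTypeParams]:
    return {
        "crop_production": FarmTypeParams(
            0.27, (3, 6), (6.0, 0.5), 0.05, 0.15, []
        ),
        "dairy_cattle": FarmTypeParams(
            0.07, (4, 7), (5.0, 0.5), 0.30, 0.75,
            [(1.0, [("dairy_cow", 0.7, 0.3), ("other_cattle", 0.4, 0.3)])],
        ),
        "meat_cattle": FarmTypeParams(
            0.18, (3, 6), (4.0, 0.5), 0.40, 0.70,
            [(1.0, [("other_cattle", 0.9, 0.4)])],
        ),
        "mixed_cattle": FarmTypeParams(
            0.01, (3, 6), (4.5, 0.5), 0.35, 0.70,
            [(1.0, [("dairy_cow", 0.35, 0.3), ("other_cattle", 0.5, 0.3)])],
        ),
        "sheep": FarmTypeParams(
            0.06, (2, 5), (2.5, 0.5), 0.45, 0.60,
            [(1.0, [("sheep", 5.0, 0.4)])],
        ),
        "pigs": FarmTypeParams(
            0.01, (3, 6), (7.0, 0.4), 0.03, 0.10,
            [(1.0, [("pig", 2.5, 0.5)])],
        ),
        "poultry": FarmTypeParams(
            0.01, (3, 6), (7.0, 0.4), 0.03, 0.10,
            [(1.0, [("poultry", 80.0, 0.5)])],
        ),
        "mixed_livestock": FarmTypeParams(
            0.03, (3, 6), (3.5, 0.5), 0.35, 0.65,
            [(1.0, [("other_cattle", 0.4, 0.3), ("sheep", 2.0, 0.4)])],
        ),
        "mixed_farming": FarmTypeParams(
            0.09, (3, 6), (4.5, 0.5), 0.25, 0.40,
            [(0.70, [("other_cattle", 0.35, 0.4)]), (0.15, [("horse", 0.2, 0.4)])],
        ),
        "small_scale": FarmTypeParams(
            0.27, (1, 3), (2.0, 0.5), 0.35, 0.50,
            [
                (0.35, [("horse", 0.25, 0.4)]),
                (0.20, [("sheep", 2.0, 0.4)]),
                (0.15, [("other_cattle", 0.3, 0.4)]),
            ],
        ),
    }


@dataclass
class SimulationConfig:
    """World-level generative parameters; defaults give a 40 km x 40 km world
    with 500 farms and Sweden-like qualitative contrasts between types."""

    extent_m: float = 70_000.0
    n_farms: int = 500
    cell_m: float = 400.0  # parcel-lattice pitch
    types: dict[str, FarmTypeParams] = field(default_factory=_default_types)
    matrix_seeds_per_km2: float = 0.3
    matrix_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "forest": 0.55,
            "other_open": 0.20,
            "water": 0.15,
            "built_up": 0.10,
        }
    )
    road_density_m_per_km2: float = 500.0
    road_segment_km: tuple[float, float] = (3.0, 8.0)
    pop_cell_m: float = 1_000.0
    pop_base_per_km2: float = 600.0
    pop_gradient_scale_m: float = 12_000.0
    pop_noise_sigma: float = 0.5
    visitor_intensity_per_km2: dict[str, float] = field(
        default_factory=lambda: {"photo": 0.5, "species_observation": 1.5}
    )
    points_per_user: float = 3.0
    protected_coverage: dict[str, float] = field(
        default_factory=lambda: {
            "nature_reserve": 0.03,
            "natura2000": 0.04,
            "national_interest": 0.08,
        }
    )
    inventory_inclusion_prob: float = 0.30
    inventory_fraction: float = 0.5
    habitats_per_cropland_ha: float = 0.5
    missing_year_prob: float = 0.02
    incomplete_parcel_prob: float = 0.05
    missing_geometry_prob: float = 0.02
    crops: tuple[str, ...] = DEFAULT_CROPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_farms <= 0 or self.extent_m <= 0:
            raise SimulationConfigError("need positive farm count and extent")
        total = sum(t.proportion for t in self.types.values())
        if abs(total - 1.0) > 1e-6:
            raise SimulationConfigError(
                f"type proportions must sum to 1 (got {total:.4f})"
            )
        for name, val in self.visitor_intensity_per_km2.items():
            if val < 0:
                raise SimulationConfigError(f"negative visitor intensity for {name}")

    @classmethod
    def homogeneous(
        cls,
        n_farms: int = 500,
        seed: int = 0,
        mixture: dict[str, float] | None = None,
        grassland_prob: float = 0.0,
    ) -> "SimulationConfig":
        """Config whose farm-level distributions are identical across types.

        Farm type then only labels the register record (through the hours
        profile), so every downstream cluster comparison is null. Livestock
        is drawn from one shared option list for all types. Two further
        choices keep the *size* and *density* schemes null as well: parcel
        geometry is near-constant (farm size varies only through parcel
        count, so no indicator co-varies with size through parcel shape) and
        by default no semi-natural grassland is generated (the
        pasture-without-ruminants selection filter would otherwise make
        grassland type- and livestock-dependent among included farms). The
        world extent scales with the farm count at 0.05 farms per km2, at
        which neighbouring farms' 20-km reference sets overlap little enough
        that local-difference values are effectively independent and the
        cluster tests run at their nominal level; the population raster is
        coarsened to 2 km accordingly.
        """
        mixture = mixture or {
            "crop_production": 0.28,
            "dairy_cattle": 0.08,
            "meat_cattle": 0.08,
            "mixed_cattle": 0.08,
            "sheep": 0.08,
            "pigs": 0.08,
            "poultry": 0.08,
            "mixed_livestock": 0.08,
            "mixed_farming": 0.08,
            "small_scale": 0.08,
        }
        shared = dict(
            parcel_count=(1, 6),
            parcel_area_ha=(4.0, 0.1),
            grassland_parcel_prob=grassland_prob,
            ley_affinity=0.45,
            livestock_options=[
                (0.25, [("other_cattle", 0.6, 0.4)]),
                (0.12, [("sheep", 3.0, 0.4)]),
                (0.12, [("horse", 0.25, 0.4)]),
                (0.08, [("pig", 2.0, 0.5)]),
            ],
        )
        types = {
            name: FarmTypeParams(proportion=prop, **copy.deepcopy(shared))
            for name, prop in mixture.items()
        }
        extent = float(np.sqrt(n_farms / 0.05) * 1000.0)
        return cls(
            n_farms=n_farms,
            extent_m=extent,
            types=types,
            pop_cell_m=2000.0,
            seed=seed,
        )


@dataclass
class PlantedEffect:
    """A standardized shift of one indicator for one farm group.

    *group* selects farms: ``type:<detailed>``, ``general:<general>``,
    ``size:s<k>`` (k of 5 exact size clusters, ascending) or
    ``density:<category>:d<k>``. *delta* is in units of the indicator's
    residual (pre-plant, across-farm) standard deviation.
    """

    group: str
    indicator: str
    delta: float

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(
                f"unknown indicator {self.indicator!r}; expected one of {INDICATORS}"
            )


@dataclass
class LandscapeBundle:
    """Everything the analysis pipeline consumes, on one planar world."""

    extent_m: float
    patches: list[LandCoverPatch]
    roads: list[RoadLine]
    pop_cells: list[Polygon]
    pop_values: list[float]
    visitor_points: list[UserPoint]
    protected: dict[str, list[Polygon]]
    inventory: list[Polygon]
    habitats: list[SmallScaleHabitat]
    records: list[dict]
    parcels: list[Parcel]
    meta: dict

    def protected_unions(self) -> dict[str, MultiPolygon]:
        return {
            name: unary_union(polys) if polys else MultiPolygon()
            for name, polys in self.protected.items()
        }

    def inventory_union(self):
        return unary_union(self.inventory) if self.inventory else MultiPolygon()

    def farms(self, cfg: AnalysisConfig | None = None) -> list[Farm]:
        return build_farms(self.records, self.parcels, cfg)


# ---------------------------------------------------------------------------
# generation helpers


def _draw_types(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    names = sorted(cfg.types)
    probs = np.array([cfg.types[n].proportion for n in names])
    return [names[i] for i in rng.choice(len(names), size=cfg.n_farms, p=probs)]


def _make_hours(farm_type: str, rng: np.random.Generator) -> dict[str, float]:
    """Enterprise hours consistent with the typology rules for *farm_type*."""

    def split(total: float, shares: dict[str, float]) -> dict[str, float]:
        return {k: round(total * v, 1) for k, v in shares.items() if v > 0}

    specialist_activity = {
        "crop_production": "crops",
        "dairy_cattle": "dairy",
        "meat_cattle": "meat_cattle",
        "sheep": "sheep",
        "pigs": "pigs",
        "poultry": "poultry",
    }
    if farm_type == "small_scale":
        return {"crops": round(float(rng.uniform(50, 390)), 1)}
    total = float(rng.uniform(700, 3000))
    if farm_type in specialist_activity:
        main = specialist_activity[farm_type]
        share = float(rng.uniform(0.72, 0.95))
        other = "crops" if main != "crops" else "dairy"
        return split(total, {main: share, other: 1 - share})
    if farm_type == "mixed_cattle":
        dairy = float(rng.uniform(0.30, 0.45))
        meat = float(rng.uniform(0.72, 0.90)) - dairy
        return split(total, {"dairy": dairy, "meat_cattle": meat,
                             "crops": 1 - dairy - meat})
    if farm_type == "mixed_livestock":
        a = float(rng.uniform(0.35, 0.50))
        b = float(rng.uniform(0.75, 0.92)) - a
        return split(total, {"meat_cattle": a, "sheep": b, "crops": 1 - a - b})
    # mixed_farming: neither crops nor all-livestock above two-thirds
    crops = float(rng.uniform(0.38, 0.62))
    return split(total, {"crops": crops, "meat_cattle": 1 - crops})


def _rect_in_cell(
    cell_ij: tuple[int, int],
    area_ha: float,
    cell_m: float,
    margin: float,
    rng: np.random.Generator,
) -> Polygon:
    avail = cell_m - 2 * margin
    area = min(area_ha * 1e4, avail * avail * 0.98)
    ratio = float(rng.uniform(0.6, 1.6))
    w = min(float(np.sqrt(area * ratio)), avail)
    h = min(area / w, avail)
    ox = cell_ij[0] * cell_m + margin + float(rng.uniform(0, avail - w))
    oy = cell_ij[1] * cell_m + margin + float(rng.uniform(0, avail - h))
    return box(ox, oy, ox + w, oy + h)


def _place_parcels(
    cfg: SimulationConfig, types: list[str]
) -> tuple[list[list[Polygon]], np.random.Generator]:
    """Rectangular parcels per farm on the lattice; farms stay spatially
    compact (anchor cell plus nearest free cells in expanding rings)."""
    rng = _rng(cfg.seed, "parcels")
    n_side = int(cfg.extent_m // cfg.cell_m)
    free = np.ones((n_side, n_side), dtype=bool)
    margin = min(20.0, cfg.cell_m * 0.05)
    out: list[list[Polygon]] = []
    for ft in types:
        params = cfg.types[ft]
        count = int(rng.integers(params.parcel_count[0], params.parcel_count[1] + 1))
        flat_free = np.flatnonzero(free.ravel())
        if flat_free.size == 0:
            raise SimulationConfigError("world too small for the farm count")
        anchor = int(flat_free[rng.integers(flat_free.size)])
        ai, aj = divmod(anchor, n_side)
        cells: list[tuple[int, int]] = []
        for ring in range(0, n_side):
            if len(cells) >= count:
                break
            lo_i, hi_i = max(0, ai - ring), min(n_side - 1, ai + ring)
            lo_j, hi_j = max(0, aj - ring), min(n_side - 1, aj + ring)
            ring_cells = [
                (i, j)
                for i in range(lo_i, hi_i + 1)
                for j in range(lo_j, hi_j + 1)
                if max(abs(i - ai), abs(j - aj)) == ring and free[i, j]
            ]
            for c in ring_cells:
                if len(cells) >= count:
                    break
                cells.append(c)
                free[c] = False
        polys = []
        med, sig = params.parcel_area_ha
        for c in cells:
            area = float(med * np.exp(rng.normal(0.0, sig)))
            polys.append(_rect_in_cell(c, max(area, 0.3), cfg.cell_m, margin, rng))
        out.append(polys)
    return out, rng


def _crop_sequence(
    affinity: float, crops: Sequence[str], years: int, rng: np.random.Generator
) -> list[str]:
    arable = [c for c in crops if c != "ley"]
    p_stay = 0.3 + 0.65 * affinity
    p_enter = 0.1 + 0.55 * affinity
    seq = []
    state = "ley" if rng.random() < affinity else arable[rng.integers(len(arable))]
    for _ in range(years):
        seq.append(state)
        if state == "ley":
            state = "ley" if rng.random() < p_stay else arable[rng.integers(len(arable))]
        else:
            state = "ley" if rng.random() < p_enter else arable[rng.integers(len(arable))]
    return seq


def _matrix_mosaic(cfg: SimulationConfig, parcels: list[Polygon]) -> list[LandCoverPatch]:
    """Voronoi partition of the non-farm matrix, classed per seed point."""
    rng = _rng(cfg.seed, "matrix")
    area_km2 = (cfg.extent_m / 1000.0) ** 2
    n_seeds = max(4, int(round(cfg.matrix_seeds_per_km2 * area_km2)))
    pts = rng.uniform(0, cfg.extent_m, size=(n_seeds, 2))
    classes = sorted(cfg.matrix_class_probs)
    probs = np.array([cfg.matrix_class_probs[c] for c in classes])
    probs = probs / probs.sum()
    seed_class = [classes[i] for i in rng.choice(len(classes), size=n_seeds, p=probs)]
    world = box(0, 0, cfg.extent_m, cfg.extent_m)
    cells = voronoi_diagram(MultiPoint(pts), envelope=world)
    # map each returned cell back to its seed for deterministic class/order
    seed_points = [Point(p) for p in pts]
    tree = STRtree(seed_points)
    indexed: list[tuple[int, Polygon]] = []
    for cell in cells.geoms:
        inside = tree.query(cell, predicate="covers")
        si = int(inside[0]) if len(inside) else int(tree.nearest(cell.centroid))
        indexed.append((si, cell.intersection(world)))
    indexed.sort(key=lambda t: t[0])
    parcel_tree = STRtree(parcels)
    patches = []
    for si, cell in indexed:
        if cell.is_empty:
            continue
        hit = parcel_tree.query(cell, predicate="intersects")
        geom = cell
        if len(hit):
            geom = cell.difference(unary_union([parcels[i] for i in sorted(hit)]))
        if geom.is_empty:
            continue
        polys = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
        for k, g in enumerate(polys):
            if g.area < 1.0:
                continue
            patches.append(
                LandCoverPatch(g, seed_class[si], f"m{si:05d}_{k}")
            )
    return patches


def _roads(cfg: SimulationConfig) -> list[RoadLine]:
    rng = _rng(cfg.seed, "roads")
    area_km2 = (cfg.extent_m / 1000.0) ** 2
    target = cfg.road_density_m_per_km2 * area_km2
    world = box(0, 0, cfg.extent_m, cfg.extent_m)
    roads: list[RoadLine] = []
    total, i = 0.0, 0
    while total < target and i < 100_000:
        x, y = rng.uniform(0, cfg.extent_m, size=2)
        ang = rng.uniform(0, np.pi)
        half = 500.0 * float(
            rng.uniform(cfg.road_segment_km[0], cfg.road_segment_km[1])
        )
        dx, dy = np.cos(ang) * half, np.sin(ang) * half
        seg = LineString([(x - dx, y - dy), (x + dx, y + dy)]).intersection(world)
        i += 1
        if seg.is_empty or seg.length < 100:
            continue
        roads.append(RoadLine(seg, f"r{len(roads):05d}"))
        total += seg.length
    return roads


def _population(cfg: SimulationConfig) -> tuple[list[Polygon], list[float]]:
    rng = _rng(cfg.seed, "population")
    n = int(cfg.extent_m // cfg.pop_cell_m)
    centre = rng.uniform(0.2 * cfg.extent_m, 0.8 * cfg.extent_m, size=2)
    cells, values = [], []
    for i in range(n):
        for j in range(n):
            x0, y0 = i * cfg.pop_cell_m, j * cfg.pop_cell_m
            cells.append(box(x0, y0, x0 + cfg.pop_cell_m, y0 + cfg.pop_cell_m))
            cx, cy = x0 + cfg.pop_cell_m / 2, y0 + cfg.pop_cell_m / 2
            dist = float(np.hypot(cx - centre[0], cy - centre[1]))
            base = cfg.pop_base_per_km2 * np.exp(-dist / cfg.pop_gradient_scale_m)
            noise = float(np.exp(rng.normal(0.0, cfg.pop_noise_sigma)))
            values.append(round(base * noise, 3))
    return cells, values


def _visitors(cfg: SimulationConfig) -> list[UserPoint]:
    rng = _rng(cfg.seed, "visitors")
    area_km2 = (cfg.extent_m / 1000.0) ** 2
    out: list[UserPoint] = []
    prefix = {"photo": "ph", "species_observation": "ob"}
    for source in sorted(cfg.visitor_intensity_per_km2):
        lam = cfg.visitor_intensity_per_km2[source] * area_km2
        n_pts = int(rng.poisson(lam))
        if n_pts == 0:
            continue
        n_users = max(1, int(round(n_pts / cfg.points_per_user)))
        user_of = rng.integers(0, n_users, size=n_pts)
        xy = rng.uniform(0, cfg.extent_m, size=(n_pts, 2))
        for k in range(n_pts):
            out.append(
                UserPoint(
                    Point(xy[k]), f"{prefix[source]}{int(user_of[k]):05d}", source
                )
            )
    return out


def _protected(cfg: SimulationConfig) -> dict[str, list[Polygon]]:
    rng = _rng(cfg.seed, "protected")
    world_area = cfg.extent_m**2
    out: dict[str, list[Polygon]] = {}
    for layer in sorted(cfg.protected_coverage):
        frac = cfg.protected_coverage[layer]
        polys: list[Polygon] = []
        covered = 0.0
        while covered < frac * world_area:
            cx, cy = rng.uniform(0, cfg.extent_m, size=2)
            side = float(1000.0 * np.exp(rng.normal(np.log(0.6), 0.4)))
            rect = box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
            rect = rect.intersection(box(0, 0, cfg.extent_m, cfg.extent_m))
            if rect.is_empty:
                continue
            polys.append(rect)
            covered += rect.area
        out[layer] = polys
    return out


# ---------------------------------------------------------------------------


def simulate(cfg: SimulationConfig) -> LandscapeBundle:
    """Generate a complete landscape bundle; deterministic given cfg.seed."""
    rng_farm = _rng(cfg.seed, "farms")
    types = _draw_types(cfg, rng_farm)
    parcel_polys, rng_parcel = _place_parcels(cfg, types)

    records: list[dict] = []
    parcels: list[Parcel] = []
    rng_seq = _rng(cfg.seed, "sequences")
    rng_live = _rng(cfg.seed, "livestock")
    pid = 0
    for f_idx, (ft, polys) in enumerate(zip(types, parcel_polys)):
        farm_id = f"f{f_idx:04d}"
        params = cfg.types[ft]
        # register record
        hours = _make_hours(ft, rng_farm)
        counts: dict[str, float] = {}
        agri_ha = sum(p.area for p in polys) / 1e4
        u = rng_live.random()
        acc = 0.0
        for prob, species_list in params.livestock_options:
            acc += prob
            if u < acc:
                for species, med, sig in species_list:
                    rate = med * float(np.exp(rng_live.normal(0.0, sig)))
                    head = int(round(rate * max(agri_ha, 1.0)))
                    if head > 0:
                        counts[species] = head
                break
        records.append({"farm_id": farm_id, "hours": hours, "counts": counts})
        if rng_farm.random() < cfg.missing_geometry_prob:
            continue  # register/IACS non-match: no parcels emitted
        for poly in polys:
            land_use = (
                "semi_natural_grassland"
                if rng_parcel.random() < params.grassland_parcel_prob
                else "cropland"
            )
            seq: Optional[tuple[Optional[str], ...]] = None
            if land_use == "cropland":
                if rng_seq.random() < cfg.incomplete_parcel_prob:
                    seq = tuple([None] * 7)
                else:
                    raw = _crop_sequence(params.ley_affinity, cfg.crops, 7, rng_seq)
                    seq = tuple(
                        None if rng_seq.random() < cfg.missing_year_prob else c
                        for c in raw
                    )
            parcels.append(
                Parcel(f"p{pid:05d}", farm_id, poly, land_use, seq)
            )
            pid += 1

    patches = _matrix_mosaic(cfg, [p.geometry for p in parcels])
    for p in parcels:
        cls = "cropland" if p.land_use == "cropland" else "semi_natural_grassland"
        patches.append(LandCoverPatch(p.geometry, cls, p.parcel_id))

    rng_inv = _rng(cfg.seed, "inventory")
    inventory: list[Polygon] = []
    for p in parcels:
        if p.land_use != "semi_natural_grassland":
            continue
        if rng_inv.random() < cfg.inventory_inclusion_prob:
            minx, miny, maxx, maxy = p.geometry.bounds
            cut = minx + (maxx - minx) * cfg.inventory_fraction
            inventory.append(box(minx, miny, cut, maxy))

    rng_hab = _rng(cfg.seed, "habitats")
    habitats: list[SmallScaleHabitat] = []
    for p in parcels:
        if p.land_use != "cropland":
            continue
        n_h = int(rng_hab.poisson(cfg.habitats_per_cropland_ha * p.area_ha))
        if n_h == 0:
            continue
        minx, miny, maxx, maxy = p.geometry.bounds
        xs = rng_hab.uniform(minx, maxx, n_h)
        ys = rng_hab.uniform(miny, maxy, n_h)
        for x, y in zip(xs, ys):
            habitats.append(SmallScaleHabitat(Point(x, y), "field_islet"))

    pop_cells, pop_values = _population(cfg)
    bundle = LandscapeBundle(
        extent_m=cfg.extent_m,
        patches=patches,
        roads=_roads(cfg),
        pop_cells=pop_cells,
        pop_values=pop_values,
        visitor_points=_visitors(cfg),
        protected=_protected(cfg),
        inventory=inventory,
        habitats=habitats,
        records=records,
        parcels=parcels,
        meta={"seed": cfg.seed, "config": config_to_dict(cfg)},
    )
    return bundle


# ---------------------------------------------------------------------------
# planted effects


def _group_farm_ids(bundle: LandscapeBundle, group: str) -> set[str]:
    from .clustering import cluster_density, cluster_size

    farms = bundle.farms()
    parts = group.split(":")
    if parts[0] == "type":
        return {f.farm_id for f in farms if f.farm_type == parts[1]}
    if parts[0] == "general":
        return {f.farm_id for f in farms if f.general_type == parts[1]}
    if parts[0] == "size":
        with_parcels = [f for f in farms if f.parcels]
        assignment = cluster_size(with_parcels, k=5)
        return set(assignment.cluster_farms(parts[1]))
    if parts[0] == "density":
        category, label = parts[1], parts[2]
        eligible = [
            f
            for f in farms
            if f.parcels and (f.lsu == 0 or f.livestock_categories() == {category})
        ]
        assignment = cluster_density(eligible, category)
        return set(assignment.cluster_farms(label))
    raise ValueError(f"unknown planted-effect group {group!r}")


def _raw_indicator_for_plant(bundle: LandscapeBundle, indicator: str) -> pd.Series:
    """Cheap per-farm raw values of the plantable indicators (drivers the
    generator controls), used to size the shift in residual-SD units.

    The residual SD is taken over the farms that pass the selection filters —
    the population the downstream analysis sees."""
    from .registry import select_farms

    farms, _ = select_farms([f for f in bundle.farms() if f.parcels])
    inv = bundle.inventory_union()
    out = {}
    if indicator == "Gra":
        for f in farms:
            A = f.agricultural_area_ha
            grass = [p.geometry for p in f.grassland_parcels]
            G = sum(g.area for g in grass) / 1e4
            O = (
                sum(g.intersection(inv).area for g in grass) / 1e4
                if grass and not inv.is_empty
                else 0.0
            )
            out[f.farm_id] = (G + O) / A if A > 0 else np.nan
    elif indicator == "SSHab":
        tree = STRtree([h.location for h in bundle.habitats])
        for f in farms:
            ha = f.cropland_area_ha
            if ha <= 0:
                out[f.farm_id] = np.nan
                continue
            hit: set[int] = set()
            for p in f.cropland_parcels:
                hit.update(tree.query(p.geometry, predicate="covers").tolist())
            out[f.farm_id] = len(hit) / ha
    elif indicator in ("Visit", "NatRes", "LanVar"):
        # per-farm parcel-union extent serves as the sizing window
        from .registry import build_study_area

        for f in farms:
            study = build_study_area(f)
            if indicator == "Visit":
                tree = STRtree([p.location for p in bundle.visitor_points])
                idx = tree.query(study.polygons, predicate="covers")
                users = {bundle.visitor_points[i].user_id for i in idx}
                out[f.farm_id] = len(users) / (study.polygons.area / 1e6)
            elif indicator == "NatRes":
                total = 0.0
                for polys in bundle.protected.values():
                    if polys:
                        total += study.polygons.intersection(unary_union(polys)).area
                out[f.farm_id] = total / study.polygons.area
            else:  # LanVar
                from .geometry import shared_border_length

                out[f.farm_id] = (
                    shared_border_length(
                        bundle.patches, window=study.polygons, validate=False
                    )
                    / study.area_ha
                )
    else:
        raise ValueError(
            f"planted effects are not supported for {indicator}: the generator "
            "does not control its raw driver directly"
        )
    return pd.Series(out)


def _split_rect(geom: Polygon, right_area_m2: float) -> tuple[Polygon, Polygon]:
    """Split an axis-aligned rectangle by a vertical line so the right part
    has exactly *right_area_m2*."""
    minx, miny, maxx, maxy = geom.bounds
    height = maxy - miny
    cut = maxx - right_area_m2 / height
    return box(minx, miny, cut, maxy), box(cut, miny, maxx, maxy)


def apply_planted_effects(
    bundle: LandscapeBundle, effects: Sequence[PlantedEffect], seed: int = 0
) -> LandscapeBundle:
    """Return a new bundle with each effect's group shifted by delta residual
    SDs on the raw indicator scale. The input bundle is not modified.

    Mechanisms: Gra — a slice of one cropland parcel is reclassified to
    semi-natural grassland (total agricultural area unchanged, so the shift
    is exact); SSHab — habitat points added inside cropland; Visit — points
    from new unique users added inside parcels; NatRes — a protected
    rectangle added inside a parcel; LanVar — cropland mosaic patches split
    into strips of alternating class to add border length.
    """
    out = copy.deepcopy(bundle)
    rng = _rng(seed, "planted")
    for e_idx, eff in enumerate(effects):
        if eff.delta == 0:
            continue
        targets = _group_farm_ids(out, eff.group)
        raw = _raw_indicator_for_plant(out, eff.indicator)
        sigma = float(raw.dropna().std(ddof=0))
        if sigma == 0 or not np.isfinite(sigma):
            raise ValueError(
                f"cannot size planted effect: {eff.indicator} has zero spread"
            )
        shift = eff.delta * sigma
        farms = {f.farm_id: f for f in out.farms() if f.parcels}
        patch_by_id = {p.patch_id: i for i, p in enumerate(out.patches)}
        for fid in sorted(targets):
            farm = farms.get(fid)
            if farm is None:
                continue
            if eff.indicator == "Gra":
                _plant_gra(out, farm, shift, patch_by_id)
            elif eff.indicator == "SSHab":
                _plant_sshab(out, farm, shift, rng)
            elif eff.indicator == "Visit":
                _plant_visit(out, farm, shift, rng, e_idx)
            elif eff.indicator == "NatRes":
                _plant_natres(out, farm, shift)
            elif eff.indicator == "LanVar":
                _plant_lanvar(out, farm, shift, patch_by_id)
    out.meta = dict(out.meta)
    out.meta["planted_effects"] = [dataclasses.asdict(e) for e in effects]
    return out


def _plant_gra(bundle, farm, shift, patch_by_id) -> None:
    need_ha = shift * farm.agricultural_area_ha  # numerator hectares to add
    croplands = sorted(farm.cropland_parcels, key=lambda p: -p.area_ha)
    for parcel in croplands:
        if need_ha <= 1e-9:
            break
        take = min(need_ha, parcel.area_ha - 0.05)
        if take <= 0:
            continue
        left, right = _split_rect(parcel.geometry, take * 1e4)
        parcel.geometry = left
        new = Parcel(
            parcel.parcel_id + "g",
            farm.farm_id,
            right,
            "semi_natural_grassland",
            None,
        )
        bundle.parcels.append(new)
        i = patch_by_id.get(parcel.parcel_id)
        if i is not None:
            bundle.patches[i] = LandCoverPatch(left, "cropland", parcel.parcel_id)
        bundle.patches.append(
            LandCoverPatch(right, "semi_natural_grassland", new.parcel_id)
        )
        need_ha -= take


def _plant_sshab(bundle, farm, shift, rng) -> None:
    n_new = int(round(shift * farm.cropland_area_ha))
    croplands = farm.cropland_parcels
    if not croplands or n_new <= 0:
        return
    areas = np.array([p.area_ha for p in croplands])
    probs = areas / areas.sum()
    for _ in range(n_new):
        parcel = croplands[int(rng.choice(len(croplands), p=probs))]
        minx, miny, maxx, maxy = parcel.geometry.bounds
        pt = Point(float(rng.uniform(minx, maxx)), float(rng.uniform(miny, maxy)))
        bundle.habitats.append(SmallScaleHabitat(pt, "field_islet"))


def _plant_visit(bundle, farm, shift, rng, e_idx) -> None:
    from .registry import build_study_area

    study = build_study_area(farm)
    n_new = int(round(shift * study.polygons.area / 1e6))
    if n_new <= 0:
        return
    parcels = farm.parcels
    areas = np.array([p.area_ha for p in parcels])
    probs = areas / areas.sum()
    for k in range(n_new):
        parcel = parcels[int(rng.choice(len(parcels), p=probs))]
        minx, miny, maxx, maxy = parcel.geometry.bounds
        pt = Point(float(rng.uniform(minx, maxx)), float(rng.uniform(miny, maxy)))
        source = "photo" if rng.random() < 0.5 else "species_observation"
        bundle.visitor_points.append(
            UserPoint(pt, f"pl{e_idx}_{farm.farm_id}_{k}", source)
        )


def _plant_natres(bundle, farm, shift) -> None:
    parcels = sorted(farm.parcels, key=lambda p: -p.area_ha)
    from .registry import build_study_area

    study = build_study_area(farm)
    need_m2 = shift * study.polygons.area
    layer = bundle.protected.setdefault("nature_reserve", [])
    for parcel in parcels:
        if need_m2 <= 1e-6:
            break
        take = min(need_m2, parcel.geometry.area)
        _, right = _split_rect(parcel.geometry, take)
        layer.append(right)
        need_m2 -= take


def _plant_lanvar(bundle, farm, shift, patch_by_id) -> None:
    from .registry import build_study_area

    study = build_study_area(farm)
    need_m = shift * study.area_ha  # border metres to add
    for parcel in sorted(farm.cropland_parcels, key=lambda p: -p.area_ha):
        if need_m <= 0:
            break
        i = patch_by_id.get(parcel.parcel_id)
        if i is None:
            continue
        minx, miny, maxx, maxy = parcel.geometry.bounds
        height = maxy - miny
        width = maxx - minx
        n_cuts = min(int(np.ceil(need_m / height)), max(int(width // 30) - 1, 0))
        if n_cuts <= 0:
            continue
        xs = np.linspace(minx, maxx, n_cuts + 2)
        strips = []
        for k in range(n_cuts + 1):
            cls = "cropland" if k % 2 == 0 else "other_open"
            strips.append(
                LandCoverPatch(
                    box(xs[k], miny, xs[k + 1], maxy), cls, f"{parcel.parcel_id}s{k}"
                )
            )
        bundle.patches[i] = strips[0]
        bundle.patches.extend(strips[1:])
        need_m -= n_cuts * height


# ---------------------------------------------------------------------------
# serialisation


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["types"] = {k: dataclasses.asdict(v) for k, v in cfg.types.items()}
    for t in d["types"].values():
        t["parcel_count"] = list(t["parcel_count"])
        t["parcel_area_ha"] = list(t["parcel_area_ha"])
        t["livestock_options"] = [
            [p, [list(s) for s in sl]] for p, sl in t["livestock_options"]
        ]
    d["crops"] = list(d["crops"])
    d["road_segment_km"] = list(d["road_segment_km"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = copy.deepcopy(d)
    types = {}
    for name, t in d.pop("types", {}).items():
        t["parcel_count"] = tuple(t["parcel_count"])
        t["parcel_area_ha"] = tuple(t["parcel_area_ha"])
        t["livestock_options"] = [
            (p, [tuple(s) for s in sl]) for p, sl in t["livestock_options"]
        ]
        types[name] = FarmTypeParams(**t)
    d["types"] = types or _default_types()
    if "crops" in d:
        d["crops"] = tuple(d["crops"])
    if "road_segment_km" in d:
        d["road_segment_km"] = tuple(d["road_segment_km"])
    return SimulationConfig(**d)


def write_bundle(bundle: LandscapeBundle, directory: Path | str) -> list[Path]:
    """Write the bundle as GeoJSON + CSV + YAML; round-trips losslessly."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def _w(name, geoms, props):
        path = d / name
        write_feature_collection(path, geoms, props)
        files.append(path)

    _w(
        "landcover.geojson",
        [p.geometry for p in bundle.patches],
        [{"class": p.patch_class, "patch_id": p.patch_id} for p in bundle.patches],
    )
    _w(
        "roads.geojson",
        [r.geometry for r in bundle.roads],
        [{"road_id": r.road_id} for r in bundle.roads],
    )
    for layer in sorted(bundle.protected):
        _w(f"protected_{layer}.geojson", bundle.protected[layer],
           [{} for _ in bundle.protected[layer]])
    _w("inventory.geojson", bundle.inventory, [{} for _ in bundle.inventory])
    _w(
        "visitors.geojson",
        [p.location for p in bundle.visitor_points],
        [{"user_id": p.user_id, "source": p.source} for p in bundle.visitor_points],
    )
    _w(
        "habitats.geojson",
        [h.location for h in bundle.habitats],
        [{"kind": h.kind} for h in bundle.habitats],
    )
    _w(
        "parcels.geojson",
        [p.geometry for p in bundle.parcels],
        [
            {"parcel_id": p.parcel_id, "farm_id": p.farm_id, "land_use": p.land_use}
            for p in bundle.parcels
        ],
    )

    pop = pd.DataFrame(
        {
            "x": [c.bounds[0] for c in bundle.pop_cells],
            "y": [c.bounds[1] for c in bundle.pop_cells],
            "size_m": [c.bounds[2] - c.bounds[0] for c in bundle.pop_cells],
            "density": bundle.pop_values,
        }
    )
    pop.to_csv(d / "population.csv", index=False)
    files.append(d / "population.csv")

    activities = sorted({a for r in bundle.records for a in r["hours"]})
    species = sorted({s for r in bundle.records for s in r["counts"]})
    rows = []
    for r in bundle.records:
        row = {"farm_id": r["farm_id"]}
        for a in activities:
            row[f"hours_{a}"] = r["hours"].get(a, 0.0)
        for s in species:
            row[f"n_{s}"] = r["counts"].get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(d / "farms.csv", index=False)
    files.append(d / "farms.csv")

    seq_rows = []
    for p in bundle.parcels:
        if p.crop_sequence is None:
            continue
        for year, crop in enumerate(p.crop_sequence):
            seq_rows.append(
                {"parcel_id": p.parcel_id, "year": year, "crop_code": crop or ""}
            )
    pd.DataFrame(seq_rows, columns=["parcel_id", "year", "crop_code"]).to_csv(
        d / "crop_sequences.csv", index=False
    )
    files.append(d / "crop_sequences.csv")

    with open(d / "meta.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"extent_m": bundle.extent_m, **bundle.meta}, fh, sort_keys=True
        )
    files.append(d / "meta.yaml")
    return files


def read_bundle(directory: Path | str) -> LandscapeBundle:
    d = Path(directory)
    with open(d / "meta.yaml", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    extent = float(meta.pop("extent_m"))

    geoms, props = read_feature_collection(d / "landcover.geojson")
    patches = [
        LandCoverPatch(g, p["class"], p["patch_id"]) for g, p in zip(geoms, props)
    ]
    geoms, props = read_feature_collection(d / "roads.geojson")
    roads = [RoadLine(g, p["road_id"]) for g, p in zip(geoms, props)]
    protected = {}
    for path in sorted(d.glob("protected_*.geojson")):
        layer = path.stem.removeprefix("protected_")
        protected[layer] = read_feature_collection(path)[0]
    inventory = read_feature_collection(d / "inventory.geojson")[0]
    geoms, props = read_feature_collection(d / "visitors.geojson")
    visitors = [UserPoint(g, p["user_id"], p["source"]) for g, p in zip(geoms, props)]
    geoms, props = read_feature_collection(d / "habitats.geojson")
    habitats = [SmallScaleHabitat(g, p["kind"]) for g, p in zip(geoms, props)]

    pop = pd.read_csv(d / "population.csv")
    pop_cells = [
        box(x, y, x + s, y + s) for x, y, s in zip(pop["x"], pop["y"], pop["size_m"])
    ]
    pop_values = [float(v) for v in pop["density"]]

    farms_df = pd.read_csv(d / "farms.csv")
    records = []
    for _, row in farms_df.iterrows():
        hours = {
            c.removeprefix("hours_"): float(row[c])
            for c in farms_df.columns
            if c.startswith("hours_") and row[c] > 0
        }
        counts = {
            c.removeprefix("n_"): int(row[c])
            for c in farms_df.columns
            if c.startswith("n_") and row[c] > 0
        }
        records.append({"farm_id": row["farm_id"], "hours": hours, "counts": counts})

    seq_df = pd.read_csv(d / "crop_sequences.csv", keep_default_na=False)
    seqs: dict[str, list[Optional[str]]] = {}
    for _, row in seq_df.iterrows():
        seqs.setdefault(row["parcel_id"], [None] * 7)[int(row["year"])] = (
            row["crop_code"] or None
        )
    geoms, props = read_feature_collection(d / "parcels.geojson")
    parcels = []
    for g, p in zip(geoms, props):
        seq = seqs.get(p["parcel_id"])
        parcels.append(
            Parcel(
                p["parcel_id"],
                p["farm_id"],
                g,
                p["land_use"],
                tuple(seq) if seq is not None else None,
            )
        )
    return LandscapeBundle(
        extent_m=extent,
        patches=patches,
        roads=roads,
        pop_cells=pop_cells,
        pop_values=pop_values,
        visitor_points=visitors,
        protected=protected,
        inventory=inventory,
        habitats=habitats,
        records=records,
        parcels=parcels,
        meta=meta,
    )
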