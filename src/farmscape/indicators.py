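"""The nine farm-level ecosystem-service indicators and matrix scaling.

Regulating-service indicators: LanVar (border length of land-cover patches per
study-area hectare), CrpDst (mean field-interior distance to non-cropland
habitat), Gra (semi-natural grassland per agricultural hectare, inventory
areas double-weighted), SSHab (small-scale habitats per cropland hectare),
CrpSeq (seven-year crop-sequence quality score). Cultural-service indicators:
RodVar (road-adjacent patches per study hectare), Acc (road proximity +
population density composite), Visit (unique photo / observation users per
km2 composite), NatRes (protected-area share of the study area).

Composites (Acc, Visit) are assembled from z-scaled component terms and then
re-scaled with the other columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .config import INDICATORS, AnalysisConfig, CropConfig
from .geometry import (
    LandCoverPatch,
    UserPoint,
    buffer_region,
    different_class_borders,
    mean_interior_distance,
    overlay_area,
    shared_border_length,
)
from .registry import Farm, StudyArea

#: Component columns carried alongside the nine indicators.
COMPONENT_COLUMNS = (
    "road_share",
    "pop_density",
    "photo_users_per_km2",
    "obs_users_per_km2",
)


@dataclass(frozen=True)
class SmallScaleHabitat:
    """A point landscape element within cropland (field islet, cairn, ...)."""

    location: Point
    kind: str


def lanvar(
    study: StudyArea,
    mosaic: Sequence[LandCoverPatch],
    borders: Sequence[shapely.Geometry] | None = None,
) -> float:
    """Border length between different-class patches per study hectare (m/ha)."""
    length = shared_border_length(
        mosaic, window=study.polygons, validate=False, borders=borders
    )
    return length / study.area_ha


def crpdst(
    farm: Farm,
    mosaic: Sequence[LandCoverPatch],
    spacing: float = 25.0,
) -> float:
    """Mean distance (m) from cropland interior to the nearest non-cropland
    habitat, excluding water and densely built-up areas."""
    cropland = [p.geometry for p in farm.cropland_parcels]
    if not cropland:
        return float("nan")
    target = unary_union(cropland)
    return mean_interior_distance(
        target, mosaic, excluded_classes=("water", "built_up"), spacing=spacing
    )


def gra(
    farm: Farm,
    inventory: Polygon | MultiPolygon | Iterable[Polygon],
) -> float:
    """Semi-natural grassland per agricultural hectare; grassland also present
    in the quality inventory is weighed with a factor of two (its overlap is
    added once more on top of the plain area)."""
    agri = farm.agricultural_area_ha
    if agri <= 0:
        return float("nan")
    grass = [p.geometry for p in farm.grassland_parcels]
    if not grass:
        return 0.0
    grass_ha = sum(g.area for g in grass) / 10_000.0
    overlap_ha = overlay_area(grass, inventory) / 10_000.0
    return (grass_ha + overlap_ha) / agri


def sshab(habitats: Sequence[SmallScaleHabitat], farm: Farm) -> float:
    """Small-scale habitats within cropland per cropland hectare."""
    cropland_ha = farm.cropland_area_ha
    if cropland_ha <= 0:
        return float("nan")
    cropland = [p.geometry for p in farm.cropland_parcels]
    if not habitats:
        return 0.0
    tree = STRtree([h.location for h in habitats])
    hit: set[int] = set()
    for geom in cropland:
        hit.update(tree.query(geom, predicate="covers").tolist())
    return len(hit) / cropland_ha


def crpseq_parcel(seq: Sequence[Optional[str]], cfg: CropConfig) -> float:
    """Score in [0, 1] for one complete crop sequence.

    Three weighted components: mean pairwise succession quality, return-time
    compliance (a year is compliant when its crop has not occurred before or
    when the gap since the previous occurrence is at least the minimum return
    time), and crop diversity (distinct crops - 1) / (years - 1). Raises when
    the sequence is incomplete or a code is outside the vocabulary.
    """
    if len(seq) != cfg.years or any(c is None for c in seq):
        raise ValueError("sequence incomplete; parcel should be skipped upstream")
    for c in seq:
        cfg._check(c)  # vocabulary guard
    pair = float(np.mean([cfg.s(seq[t - 1], seq[t]) for t in range(1, cfg.years)]))
    compliant = 0
    for t in range(1, cfg.years):
        prev_occurrences = [u for u in range(t) if seq[u] == seq[t]]
        if not prev_occurrences:
            compliant += 1
        elif t - prev_occurrences[-1] >= cfg.r(seq[t]):
            compliant += 1
    ret = compliant / (cfg.years - 1)
    div = (len(set(seq)) - 1) / (cfg.years - 1)
    return cfg.w_pair * pair + cfg.w_return * ret + cfg.w_div * div


def crpseq_farm(
    farm: Farm, cfg: CropConfig, coverage_threshold: float = 0.5
) -> float:
    """Area-weighted mean parcel score over complete-sequence cropland; NaN
    when complete parcels cover less than the coverage threshold."""
    cropland = farm.cropland_parcels
    total = sum(p.area_ha for p in cropland)
    if total <= 0:
        return float("nan")
    complete = [p for p in cropland if p.sequence_complete]
    covered = sum(p.area_ha for p in complete)
    if covered / total < coverage_threshold:
        return float("nan")
    scores = np.array([crpseq_parcel(p.crop_sequence, cfg) for p in complete])
    areas = np.array([p.area_ha for p in complete])
    return float((scores * areas).sum() / areas.sum())


def rodvar(
    mosaic: Sequence[LandCoverPatch],
    road_zone: Polygon | MultiPolygon,
    study: StudyArea,
    mosaic_tree: STRtree | None = None,
) -> float:
    """Distinct patches inside the study area intercepted by / adjacent to
    roads (roads dilated by the adjacency distance), per study hectare.

    *road_zone* is the pre-dilated road buffer; *mosaic_tree* an optional
    prebuilt STRtree over the mosaic geometries.
    """
    if road_zone is None or road_zone.is_empty:
        return 0.0
    tree = mosaic_tree or STRtree([p.geometry for p in mosaic])
    count = 0
    for i in tree.query(study.polygons, predicate="intersects"):
        clipped = mosaic[i].geometry.intersection(study.polygons)
        if not clipped.is_empty and clipped.intersects(road_zone):
            count += 1
    return count / study.area_ha


def acc_components(
    study: StudyArea,
    road_zone_100: Polygon | MultiPolygon | None,
    pop_cells: Sequence[Polygon],
    pop_values: Sequence[float],
    population_buffer_m: float = 10_000.0,
    arc_tolerance: float | None = None,
    pop_tree: STRtree | None = None,
) -> tuple[float, float]:
    """(road_share, pop_density) accessibility components.

    road_share: fraction of the study area within 100 m of a road (the
    pre-dilated *road_zone_100*). pop_density: area-weighted mean of the
    population raster (persons/km2) within a 10 km buffer around the study
    area.
    """
    area = study.polygons.area
    if road_zone_100 is None or road_zone_100.is_empty:
        share = 0.0
    else:
        share = study.polygons.intersection(road_zone_100).area / area
    zone = buffer_region([study.polygons], population_buffer_m, arc_tolerance)
    tree = pop_tree or STRtree(list(pop_cells))
    idx = tree.query(zone, predicate="intersects")
    if len(idx) == 0:
        return share, float("nan")
    cells = [pop_cells[i] for i in idx]
    weights = shapely.area(shapely.intersection(np.array(cells, dtype=object), zone))
    vals = np.asarray([pop_values[i] for i in idx], dtype=float)
    wsum = weights.sum()
    if wsum <= 0:
        return share, float("nan")
    return float(share), float((weights * vals).sum() / wsum)


def visit_components(
    points: Sequence[UserPoint],
    study: StudyArea,
    point_tree: STRtree | None = None,
) -> tuple[float, float]:
    """(photo users/km2, observation users/km2): distinct user ids with at
    least one point inside the study area, per study km2."""
    km2 = study.polygons.area / 1e6
    if not points:
        return 0.0, 0.0
    tree = point_tree or STRtree([p.location for p in points])
    idx = tree.query(study.polygons, predicate="covers")
    users: dict[str, set[str]] = {"photo": set(), "species_observation": set()}
    for i in idx:
        users[points[i].source].add(points[i].user_id)
    return len(users["photo"]) / km2, len(users["species_observation"]) / km2


def natres(
    protected_layers: Mapping[str, Polygon | MultiPolygon],
    study: StudyArea,
) -> float:
    """Per-layer sum of protected-area overlap divided by study area; the
    three layers add even where they overlap each other, so the ratio lies in
    [0, n_layers]."""
    area = study.polygons.area
    total = 0.0
    for layer in protected_layers.values():
        if layer is None or layer.is_empty:
            continue
        total += study.polygons.intersection(layer).area
    return total / area


# ---------------------------------------------------------------------------


def zscale(values: np.ndarray) -> np.ndarray:
    """(x - mean) / population SD over non-missing entries; a zero-variance
    column maps to zeros with a warning."""
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    if mask.sum() < 2:
        warnings.warn("fewer than 2 non-missing values; column left as NaN")
        return out
    sub = values[mask]
    sd = sub.std()  # population SD (ddof=0)
    if sd == 0:
        warnings.warn("zero-variance column scaled to all zeros")
        out[mask] = 0.0
        return out
    out[mask] = (sub - sub.mean()) / sd
    return out


def scale_matrix(raw: pd.DataFrame) -> pd.DataFrame:
    """z-scale an indicator matrix column-wise.

    Composite indicators are rebuilt first: Acc = z(road_share) +
    z(pop_density), Visit = z(photo users) + z(obs users); the composite
    columns are then re-scaled together with the plain indicators.
    """
    raw = raw.copy()
    if {"road_share", "pop_density"} <= set(raw.columns):
        raw["Acc"] = zscale(raw["road_share"].to_numpy(float)) + zscale(
            raw["pop_density"].to_numpy(float)
        )
    if {"photo_users_per_km2", "obs_users_per_km2"} <= set(raw.columns):
        raw["Visit"] = zscale(raw["photo_users_per_km2"].to_numpy(float)) + zscale(
            raw["obs_users_per_km2"].to_numpy(float)
        )
    scaled = pd.DataFrame(index=raw.index)
    for col in INDICATORS:
        if col in raw.columns:
            scaled[col] = zscale(raw[col].to_numpy(float))
    return scaled


def compute_indicator_matrix(
    farms: Sequence[Farm],
    study_areas: Mapping[str, StudyArea],
    mosaic: Sequence[LandCoverPatch],
    roads,
    pop_cells: Sequence[Polygon],
    pop_values: Sequence[float],
    visitor_points: Sequence[UserPoint],
    protected_layers: Mapping[str, Polygon | MultiPolygon],
    inventory: Polygon | MultiPolygon,
    habitats: Sequence[SmallScaleHabitat],
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Raw indicator matrix (farm x indicator + component columns).

    Shared spatial structures (patch borders, dilated road zones, STR trees)
    are built once and reused across farms.
    """
    cfg = cfg or AnalysisConfig()
    borders = different_class_borders(mosaic, validate=False)
    road_geoms = [r.geometry for r in roads]
    road_zone_100 = (
        buffer_region(road_geoms, cfg.road_distance_m, cfg.arc_tolerance_m)
        if road_geoms
        else None
    )
    road_zone_adj = None
    if road_geoms:
        road_zone_adj = (
            buffer_region(road_geoms, cfg.rodvar_adjacency_m, cfg.arc_tolerance_m)
            if cfg.rodvar_adjacency_m > 0
            else unary_union(road_geoms)
        )
    mosaic_tree = STRtree([p.geometry for p in mosaic])
    pop_tree = STRtree(list(pop_cells)) if len(pop_cells) else None
    point_tree = (
        STRtree([p.location for p in visitor_points]) if visitor_points else None
    )
    inv = inventory if inventory is not None else MultiPolygon()

    rows = []
    for farm in farms:
        study = study_areas[farm.farm_id]
        road_share, pop_density = acc_components(
            study,
            road_zone_100,
            pop_cells,
            pop_values,
            cfg.population_buffer_m,
            cfg.arc_tolerance_m,
            pop_tree=pop_tree,
        )
        photo, obs = visit_components(visitor_points, study, point_tree=point_tree)
        rows.append(
            {
                "farm_id": farm.farm_id,
                "LanVar": lanvar(study, mosaic, borders=borders),
                "CrpDst": crpdst(farm, mosaic, cfg.crpdst_spacing_m),
                "Gra": gra(farm, inv),
                "SSHab": sshab(habitats, farm),
                "CrpSeq": crpseq_farm(farm, cfg.crop_config, cfg.coverage_threshold),
                "RodVar": rodvar(mosaic, road_zone_adj, study, mosaic_tree=mosaic_tree)
                if road_zone_adj is not None
                else 0.0,
                "road_share": road_share,
                "pop_density": pop_density,
                "photo_users_per_km2": photo,
                "obs_users_per_km2": obs,
                "NatRes": natres(protected_layers, study),
            }
        )
    df = pd.DataFrame(rows).set_index("farm_id")
    # raw composites (unscaled sums) are kept for reference; the analysed Acc
    # and Visit columns are rebuilt from z-scaled components in scale_matrix
    df["Acc"] = df["road_share"] + df["pop_density"]
    df["Visit"] = df["photo_users_per_km2"] + df["obs_users_per_km2"]
    return df[list(INDICATORS) + list(COMPONENT_COLUMNS)]
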