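"""Farm typology, livestock-unit densities, selection filters and study areas.

A *farm* is the agricultural land managed by one enterprise: a register record
(standardised enterprise working hours, livestock head counts) linked to
georeferenced parcels. The *study area* is the union of the farm's parcels
dilated by 50 m — the evaluation window for most indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon

from .config import AnalysisConfig, RUMINANT_OR_HORSE
from .geometry import buffer_region, validate_polygon

#: Enterprise-hour activity vocabulary; the livestock subset drives the
#: mixed-livestock / mixed-cattle rules.
ACTIVITIES = ("crops", "dairy", "meat_cattle", "sheep", "pigs", "poultry")
LIVESTOCK_ACTIVITIES = ("dairy", "meat_cattle", "sheep", "pigs", "poultry")
CATTLE_ACTIVITIES = ("dairy", "meat_cattle")

DETAILED_TYPES = (
    "crop_production",
    "dairy_cattle",
    "meat_cattle",
    "mixed_cattle",
    "sheep",
    "pigs",
    "poultry",
    "mixed_livestock",
    "mixed_farming",
    "small_scale",
)

_ACTIVITY_TO_TYPE = {
    "crops": "crop_production",
    "dairy": "dairy_cattle",
    "meat_cattle": "meat_cattle",
    "sheep": "sheep",
    "pigs": "pigs",
    "poultry": "poultry",
}

GENERAL_OF = {
    "crop_production": "crops",
    "dairy_cattle": "ruminants",
    "meat_cattle": "ruminants",
    "mixed_cattle": "ruminants",
    "sheep": "ruminants",
    "pigs": "monogastrics",
    "poultry": "monogastrics",
    "mixed_livestock": "mixed",
    "mixed_farming": "mixed",
    "small_scale": "small_scale",
}


class ClassificationError(ValueError):
    """Raised when a farm cannot be typed (e.g. empty hour map)."""


def classify_farm_type(
    hours: Mapping[str, float],
    small_scale_hours: float = 400.0,
    specialist_share: float = 2.0 / 3.0,
) -> str:
    """Detailed farm type from standardised enterprise working hours.

    Farms below *small_scale_hours* total are small-scale. Otherwise a farm is
    a specialist type when a single activity exceeds the two-thirds share
    (strictly); combined cattle hours above the share give mixed cattle, all
    livestock above it mixed livestock, anything else mixed farming.
    """
    if not hours:
        raise ClassificationError("empty enterprise-hours map")
    for act, h in hours.items():
        if act not in ACTIVITIES:
            raise ClassificationError(f"unknown activity {act!r}")
        if h < 0:
            raise ClassificationError(f"negative hours for {act!r}")
    total = float(sum(hours.values()))
    if total < small_scale_hours:
        return "small_scale"
    shares = {a: hours.get(a, 0.0) / total for a in ACTIVITIES}
    for act, share in shares.items():
        if share > specialist_share:
            return _ACTIVITY_TO_TYPE[act]
    if sum(shares[a] for a in CATTLE_ACTIVITIES) > specialist_share:
        return "mixed_cattle"
    if sum(shares[a] for a in LIVESTOCK_ACTIVITIES) > specialist_share:
        return "mixed_livestock"
    return "mixed_farming"


def livestock_units(counts: Mapping[str, float], table: Mapping[str, float]) -> float:
    """Total livestock units: sum of head counts times LSU coefficients."""
    total = 0.0
    for species, head in counts.items():
        if head < 0:
            raise ValueError(f"negative head count for {species!r}")
        if head == 0:
            continue
        if species not in table:
            raise ValueError(f"no LSU coefficient for species {species!r}")
        total += head * table[species]
    return float(total)


@dataclass
class Parcel:
    """One agricultural parcel: geometry, land use and (for cropland) a
    seven-slot crop sequence whose entries may be None (missing)."""

    parcel_id: str
    farm_id: str
    geometry: Polygon
    land_use: str  # cropland | semi_natural_grassland
    crop_sequence: Optional[tuple[Optional[str], ...]] = None

    def __post_init__(self) -> None:
        if self.land_use not in ("cropland", "semi_natural_grassland"):
            raise ValueError(f"unknown land use {self.land_use!r}")
        validate_polygon(self.geometry)

    @property
    def area_ha(self) -> float:
        return self.geometry.area / 10_000.0

    @property
    def sequence_complete(self) -> bool:
        return self.crop_sequence is not None and all(
            c is not None for c in self.crop_sequence
        )


@dataclass
class StudyArea:
    """Union of a farm's 50 m-buffered parcels plus the farm centre point."""

    farm_id: str
    polygons: Polygon | MultiPolygon
    area_ha: float
    centre: tuple[float, float]


@dataclass
class Farm:
    """Register record linked to parcels, with derived typology and density."""

    farm_id: str
    enterprise_hours: dict[str, float]
    livestock_counts: dict[str, float]
    parcels: list[Parcel] = field(default_factory=list)
    farm_type: str = ""
    lsu: float = 0.0

    @property
    def general_type(self) -> str:
        return GENERAL_OF[self.farm_type]

    @property
    def agricultural_area_ha(self) -> float:
        return sum(p.area_ha for p in self.parcels)

    @property
    def cropland_area_ha(self) -> float:
        return sum(p.area_ha for p in self.parcels if p.land_use == "cropland")

    @property
    def grassland_parcels(self) -> list[Parcel]:
        return [p for p in self.parcels if p.land_use == "semi_natural_grassland"]

    @property
    def cropland_parcels(self) -> list[Parcel]:
        return [p for p in self.parcels if p.land_use == "cropland"]

    @property
    def lsu_density(self) -> float:
        """LSU per hectare total agricultural land; NaN when area is zero."""
        area = self.agricultural_area_ha
        return self.lsu / area if area > 0 else float("nan")

    def has_ruminants_or_horses(self) -> bool:
        return any(self.livestock_counts.get(s, 0) > 0 for s in RUMINANT_OR_HORSE)

    def livestock_categories(self) -> set[str]:
        from .config import LIVESTOCK_CATEGORIES

        return {
            LIVESTOCK_CATEGORIES[s]
            for s, n in self.livestock_counts.items()
            if n > 0 and s in LIVESTOCK_CATEGORIES
        }


def build_farms(
    records: Iterable[Mapping],
    parcels: Iterable[Parcel],
    cfg: AnalysisConfig | None = None,
) -> list[Farm]:
    """Link register records to parcels and derive type and LSU.

    Each record needs ``farm_id``, ``hours`` (activity map) and ``counts``
    (species map). Records without parcels are kept (filter ii removes them
    later).
    """
    cfg = cfg or AnalysisConfig()
    by_farm: dict[str, list[Parcel]] = {}
    for p in parcels:
        by_farm.setdefault(p.farm_id, []).append(p)
    farms = []
    for rec in records:
        farm = Farm(
            farm_id=rec["farm_id"],
            enterprise_hours=dict(rec["hours"]),
            livestock_counts=dict(rec["counts"]),
            parcels=sorted(by_farm.get(rec["farm_id"], []), key=lambda p: p.parcel_id),
        )
        farm.farm_type = classify_farm_type(
            farm.enterprise_hours, cfg.small_scale_hours, cfg.specialist_share
        )
        farm.lsu = livestock_units(farm.livestock_counts, cfg.lsu_table)
        farms.append(farm)
    return sorted(farms, key=lambda f: f.farm_id)


def complete_sequence_coverage(farm: Farm) -> float:
    """Fraction of cropland area carrying a complete seven-year crop sequence;
    1.0 for farms with no cropland (nothing to cover)."""
    cropland = farm.cropland_parcels
    total = sum(p.area_ha for p in cropland)
    if total == 0:
        return 1.0
    complete = sum(p.area_ha for p in cropland if p.sequence_complete)
    return complete / total


def select_farms(
    farms: Sequence[Farm], cfg: AnalysisConfig | None = None
) -> tuple[list[Farm], list[tuple[str, str]]]:
    """Apply the four selection filters in order; return (included, log).

    (i) no cropland; (ii) no parcel geometry linked; (iii) pasture present but
    no ruminants or horses reported; (iv) complete crop sequences derivable
    for less than the coverage threshold (default 50%) of cropland area.
    The log records ``(farm_id, rule)`` for every exclusion.
    """
    cfg = cfg or AnalysisConfig()
    included: list[Farm] = []
    log: list[tuple[str, str]] = []
    for farm in sorted(farms, key=lambda f: f.farm_id):
        if not farm.parcels:
            # (ii) before (i): without geometry, cropland is unknowable
            log.append((farm.farm_id, "ii"))
            continue
        if farm.cropland_area_ha == 0:
            log.append((farm.farm_id, "i"))
            continue
        if farm.grassland_parcels and not farm.has_ruminants_or_horses():
            log.append((farm.farm_id, "iii"))
            continue
        if complete_sequence_coverage(farm) < cfg.coverage_threshold:
            log.append((farm.farm_id, "iv"))
            continue
        included.append(farm)
    return included, log


def build_study_area(
    farm: Farm,
    buffer_m: float = 50.0,
    arc_tolerance: float | None = None,
) -> StudyArea:
    """Merged union of the farm's buffered parcels.

    The centre point is the area-weighted centroid of the *unbuffered*
    parcels, so it is stable under buffer-tolerance changes.
    """
    if not farm.parcels:
        raise ValueError(f"farm {farm.farm_id} has no parcels")
    geoms = [p.geometry for p in farm.parcels]
    merged = buffer_region(geoms, buffer_m, arc_tolerance)
    areas = np.array([g.area for g in geoms])
    cents = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
    cx, cy = (cents * areas[:, None]).sum(axis=0) / areas.sum()
    return StudyArea(
        farm_id=farm.farm_id,
        polygons=merged,
        area_ha=merged.area / 10_000.0,
        centre=(float(cx), float(cy)),
    )
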