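"""Staged pipeline: simulate -> indicators -> screen -> cluster -> compare ->
map, with per-stage artefacts, a manifest and full determinism under a fixed
seed.

Each stage writes CSV/GeoJSON artefacts into the output directory and appends
to ``manifest.yaml`` (stage name, seed, input config, SHA-256 of every file
written). Reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterAssignment,
    build_density_schemes,
    cluster_size,
    group_by_type,
)
from .comparison import compare_scheme
from .config import INDICATORS, AnalysisConfig, deviations_from_defaults
from .indicators import compute_indicator_matrix, scale_matrix
from .io import read_feature_collection, write_feature_collection
from .registry import StudyArea, build_study_area, select_farms
from .screening import exclusion_screen, grid_summary, spearman_matrix
from .synthetic import (
    LandscapeBundle,
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    read_bundle,
    simulate,
    write_bundle,
)

STAGES = ("simulate", "indicators", "screen", "cluster", "compare", "map")


class DependencyError(RuntimeError):
    """A stage was requested before the artefact it needs exists."""


@dataclass
class PipelineConfig:
    """Top-level run configuration: analysis constants + simulation block."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            analysis=AnalysisConfig.from_dict(doc.get("analysis", {})),
            simulation=config_from_dict(doc.get("simulation", {"types": {}}))
            if "simulation" in doc
            else SimulationConfig(),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "analysis": self.analysis.to_dict(),
            "simulation": config_to_dict(self.simulation),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def validate_config(path) -> dict:
    """Schema-check a YAML pipeline config; list deviations from defaults.

    Returns {"fatal": [...], "deviations": {...}, "ok": bool}. A value that
    fails a dataclass invariant is fatal; a constant merely off its study
    default is reported as a non-fatal deviation.
    """
    report: dict = {"fatal": [], "deviations": {}, "ok": True}
    try:
        cfg = PipelineConfig.from_yaml(path)
    except Exception as exc:  # schema violation
        report["fatal"].append(str(exc))
        report["ok"] = False
        return report
    report["deviations"] = {
        k: {"value": v[0], "default": v[1]}
        for k, v in deviations_from_defaults(cfg.analysis).items()
    }
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _record_manifest(out: Path, stage: str, seed: int, files: Sequence[Path]) -> None:
    manifest_path = out / "manifest.yaml"
    doc = {}
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
    doc[stage] = {
        "seed": seed,
        "version": __version__,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))},
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} needs missing artefact {path.name!r}; "
            "run the producing stage first"
        )
    return path


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, float_format="%.10g", **kw)
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out: Path, seed: int) -> LandscapeBundle:
    sim_cfg = SimulationConfig(**{**_sim_kwargs(cfg.simulation), "seed": seed})
    bundle = simulate(sim_cfg)
    files = write_bundle(bundle, out / "bundle")
    _record_manifest(out, "simulate", seed, files)
    return bundle


def _sim_kwargs(sim: SimulationConfig) -> dict:
    d = config_to_dict(sim)
    return {**config_from_dict(d).__dict__}


def _load_bundle(out: Path, stage: str) -> LandscapeBundle:
    _require(out / "bundle" / "meta.yaml", stage)
    return read_bundle(out / "bundle")


def stage_indicators(cfg: PipelineConfig, out: Path, seed: int) -> None:
    bundle = _load_bundle(out, "indicators")
    farms = bundle.farms(cfg.analysis)
    included, log = select_farms(farms, cfg.analysis)
    files = []
    files.append(
        _write_csv(
            pd.DataFrame(log, columns=["farm_id", "rule"]),
            out / "exclusions.csv",
            index=False,
        )
    )
    study_areas = {
        f.farm_id: build_study_area(
            f, cfg.analysis.study_buffer_m, cfg.analysis.arc_tolerance_m
        )
        for f in included
    }
    write_feature_collection(
        out / "study_areas.geojson",
        [study_areas[f.farm_id].polygons for f in included],
        [
            {
                "farm_id": f.farm_id,
                "area_ha": study_areas[f.farm_id].area_ha,
                "centre_x": study_areas[f.farm_id].centre[0],
                "centre_y": study_areas[f.farm_id].centre[1],
            }
            for f in included
        ],
    )
    files.append(out / "study_areas.geojson")
    raw = compute_indicator_matrix(
        included,
        study_areas,
        bundle.patches,
        bundle.roads,
        bundle.pop_cells,
        bundle.pop_values,
        bundle.visitor_points,
        bundle.protected_unions(),
        bundle.inventory_union(),
        bundle.habitats,
        cfg.analysis,
    )
    scaled = scale_matrix(raw)
    files.append(_write_csv(raw, out / "indicators_raw.csv"))
    files.append(_write_csv(scaled, out / "indicators_scaled.csv"))
    files.append(_write_csv(farm_type_summary(included), out / "farm_summary.csv"))
    areas = pd.DataFrame(
        {
            "farm_id": [f.farm_id for f in included],
            "agricultural_area_ha": [f.agricultural_area_ha for f in included],
            "cropland_area_ha": [f.cropland_area_ha for f in included],
            "farm_type": [f.farm_type for f in included],
            "general_type": [f.general_type for f in included],
            "lsu": [f.lsu for f in included],
            "lsu_density": [f.lsu_density for f in included],
        }
    )
    files.append(_write_csv(areas, out / "farm_attributes.csv", index=False))
    _record_manifest(out, "indicators", seed, files)


def farm_type_summary(farms) -> pd.DataFrame:
    """Register-style per-type summary: farm counts, areas, grassland share."""
    rows = []
    df = pd.DataFrame(
        {
            "type": [f.farm_type for f in farms],
            "general": [f.general_type for f in farms],
            "agri": [f.agricultural_area_ha for f in farms],
            "crop": [f.cropland_area_ha for f in farms],
            "grass": [
                f.agricultural_area_ha - f.cropland_area_ha for f in farms
            ],
        }
    )
    for (gen, typ), sub in df.groupby(["general", "type"]):
        rows.append(
            {
                "general_type": gen,
                "farm_type": typ,
                "n_farms": len(sub),
                "agricultural_area_ha": sub["agri"].sum(),
                "avg_area_ha": sub["agri"].mean(),
                "cropland_ha": sub["crop"].sum(),
                "grassland_ha": sub["grass"].sum(),
                "grassland_pct_of_area": 100 * sub["grass"].sum() / sub["agri"].sum()
                if sub["agri"].sum() > 0
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def stage_screen(cfg: PipelineConfig, out: Path, seed: int) -> None:
    scaled = pd.read_csv(
        _require(out / "indicators_scaled.csv", "screen"), index_col=0
    )
    corr = spearman_matrix(scaled[list(INDICATORS)], cfg.analysis)
    retained = exclusion_screen(corr, cfg.analysis.indicator_priority)
    files = [
        _write_csv(corr.r, out / "correlations.csv"),
        _write_csv(corr.p, out / "correlations_p.csv"),
        _write_csv(corr.strength, out / "correlations_strength.csv"),
    ]
    path = out / "retained_indicators.txt"
    path.write_text("\n".join(retained) + "\n", encoding="utf-8")
    files.append(path)
    _record_manifest(out, "screen", seed, files)


def _load_included_farms(cfg: PipelineConfig, out: Path, stage: str):
    bundle = _load_bundle(out, stage)
    farms = bundle.farms(cfg.analysis)
    included, _ = select_farms(farms, cfg.analysis)
    return bundle, included


def stage_cluster(cfg: PipelineConfig, out: Path, seed: int) -> None:
    _require(out / "indicators_raw.csv", "cluster")
    _, included = _load_included_farms(cfg, out, "cluster")
    schemes: list[ClusterAssignment] = [
        group_by_type(included, "general"),
        group_by_type(included, "detailed"),
        cluster_size(included, cfg.analysis.size_clusters),
    ]
    schemes += list(build_density_schemes(included, cfg.analysis).values())
    files = []
    for a in schemes:
        rows = pd.DataFrame(
            {
                "farm_id": sorted(a.labels),
                "cluster": [a.labels[f] for f in sorted(a.labels)],
                "value": [a.values[f] for f in sorted(a.labels)],
            }
        )
        files.append(_write_csv(rows, out / f"clusters_{a.scheme}.csv", index=False))
        files.append(
            _write_csv(a.summary, out / f"cluster_summary_{a.scheme}.csv", index=False)
        )
    _record_manifest(out, "cluster", seed, files)


def _load_schemes(cfg: PipelineConfig, out: Path, included) -> list[ClusterAssignment]:
    schemes = [
        group_by_type(included, "general"),
        group_by_type(included, "detailed"),
        cluster_size(included, cfg.analysis.size_clusters),
    ]
    schemes += list(build_density_schemes(included, cfg.analysis).values())
    return schemes


def stage_compare(cfg: PipelineConfig, out: Path, seed: int) -> None:
    scaled = pd.read_csv(
        _require(out / "indicators_scaled.csv", "compare"), index_col=0
    )
    geoms, props = read_feature_collection(
        _require(out / "study_areas.geojson", "compare")
    )
    study_areas = {
        p["farm_id"]: StudyArea(
            p["farm_id"], g, p["area_ha"], (p["centre_x"], p["centre_y"])
        )
        for g, p in zip(geoms, props)
    }
    attrs = pd.read_csv(out / "farm_attributes.csv").set_index("farm_id")
    areas_ha = attrs["agricultural_area_ha"].to_dict()
    retained_path = out / "retained_indicators.txt"
    indicators = (
        retained_path.read_text().split()
        if retained_path.exists()
        else list(scaled.columns)
    )
    _, included = _load_included_farms(cfg, out, "compare")
    files = []
    excluded_rows = []
    for a in _load_schemes(cfg, out, included):
        table, _ = compare_scheme(
            a, scaled, study_areas, areas_ha, cfg.analysis, indicators
        )
        files.append(
            _write_csv(table, out / f"comparison_{a.scheme}.csv", index=False)
        )
        for fid in table.attrs.get("excluded", []):
            excluded_rows.append({"scheme": a.scheme, "farm_id": fid})
    files.append(
        _write_csv(
            pd.DataFrame(excluded_rows, columns=["scheme", "farm_id"]),
            out / "comparison_excluded.csv",
            index=False,
        )
    )
    _record_manifest(out, "compare", seed, files)


def stage_map(cfg: PipelineConfig, out: Path, seed: int) -> None:
    from shapely.ops import unary_union

    from .screening import landuse_point_density, landuse_protection_share

    scaled = pd.read_csv(_require(out / "indicators_scaled.csv", "map"), index_col=0)
    geoms, props = read_feature_collection(_require(out / "study_areas.geojson", "map"))
    centres = {p["farm_id"]: (p["centre_x"], p["centre_y"]) for p in props}
    attrs = pd.read_csv(out / "farm_attributes.csv").set_index("farm_id")
    areas_ha = attrs["agricultural_area_ha"].to_dict()
    retained_path = out / "retained_indicators.txt"
    cols = (
        retained_path.read_text().split()
        if retained_path.exists()
        else list(scaled.columns)
    )
    cells = grid_summary(
        scaled[cols],
        centres,
        areas_ha,
        cfg.analysis.grid_cell_m,
        cfg.analysis.hi_percentile,
        cfg.analysis.lo_percentile,
    )
    rows = []
    for c in cells:
        row = {
            "x": c.origin[0],
            "y": c.origin[1],
            "size_m": c.size_m,
            "n_farms": c.n_farms,
            "farm_area_ha": c.farm_area_ha,
            "n_above": c.n_above,
            "n_below": c.n_below,
        }
        row.update({f"mean_{k}": v for k, v in c.means.items()})
        rows.append(row)
    files = [_write_csv(pd.DataFrame(rows), out / "grid_summary.csv", index=False)]

    bundle, included = _load_included_farms(cfg, out, "map")
    by_class: dict[str, list] = {"cropland": [], "semi_natural_grassland": []}
    study_polys = []
    for f in included:
        for p in f.parcels:
            by_class[p.land_use].append(p.geometry)
    for g, p in zip(geoms, props):
        study_polys.append(g)
    agri = unary_union(by_class["cropland"] + by_class["semi_natural_grassland"])
    outside = unary_union(study_polys).difference(agri)
    landuse = {
        "cropland": unary_union(by_class["cropland"]),
        "semi_natural_grassland": unary_union(by_class["semi_natural_grassland"]),
        "outside": outside,
    }
    files.append(
        _write_csv(
            landuse_point_density(bundle.visitor_points, landuse),
            out / "landuse_visitors.csv",
            index=False,
        )
    )
    files.append(
        _write_csv(
            landuse_protection_share(landuse, bundle.protected_unions()),
            out / "landuse_protection.csv",
            index=False,
        )
    )
    _record_manifest(out, "map", seed, files)


def analyse_bundle(
    bundle: LandscapeBundle,
    cfg: AnalysisConfig | None = None,
    schemes: Sequence[str] = ("type_general", "type_detailed", "size", "density"),
    screen: bool = True,
):
    """In-memory end-to-end analysis of one landscape bundle.

    Runs selection, study areas, indicators, scaling, optional redundancy
    screening, the requested grouping schemes and the local-reference
    comparisons. Returns a dict with included farms, raw and scaled
    matrices, retained indicator list, assignments and comparison tables.
    """
    cfg = cfg or AnalysisConfig()
    farms = bundle.farms(cfg)
    included, exclusion_log = select_farms(farms, cfg)
    study_areas = {
        f.farm_id: build_study_area(f, cfg.study_buffer_m, cfg.arc_tolerance_m)
        for f in included
    }
    raw = compute_indicator_matrix(
        included,
        study_areas,
        bundle.patches,
        bundle.roads,
        bundle.pop_cells,
        bundle.pop_values,
        bundle.visitor_points,
        bundle.protected_unions(),
        bundle.inventory_union(),
        bundle.habitats,
        cfg,
    )
    scaled = scale_matrix(raw)
    retained = list(INDICATORS)
    if screen:
        corr = spearman_matrix(scaled[list(INDICATORS)], cfg)
        retained = exclusion_screen(corr, cfg.indicator_priority)
    assignments: list[ClusterAssignment] = []
    if "type_general" in schemes:
        assignments.append(group_by_type(included, "general"))
    if "type_detailed" in schemes:
        assignments.append(group_by_type(included, "detailed"))
    if "size" in schemes:
        assignments.append(cluster_size(included, cfg.size_clusters))
    if "density" in schemes:
        assignments += list(build_density_schemes(included, cfg).values())
    areas_ha = {f.farm_id: f.agricultural_area_ha for f in included}
    comparisons = {}
    for a in assignments:
        table, d_matrix = compare_scheme(
            a, scaled, study_areas, areas_ha, cfg, retained
        )
        comparisons[a.scheme] = table
    return {
        "included": included,
        "exclusion_log": exclusion_log,
        "study_areas": study_areas,
        "raw": raw,
        "scaled": scaled,
        "retained": retained,
        "assignments": assignments,
        "comparisons": comparisons,
    }


_STAGE_FN = {
    "simulate": stage_simulate,
    "indicators": stage_indicators,
    "screen": stage_screen,
    "cluster": stage_cluster,
    "compare": stage_compare,
    "map": stage_map,
}


def run_pipeline(
    cfg: PipelineConfig,
    out_dir,
    stages: Sequence[str] = STAGES,
    seed: int | None = None,
) -> Path:
    """Execute the requested stages in dependency order; returns the out dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else cfg.simulation.seed)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:
        if stage in stages:
            _STAGE_FN[stage](cfg, out, seed)
    return out
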