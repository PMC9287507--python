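"""Calibration experiments: type-I error control and planted-effect recovery.

Two simulation experiments validate the comparison machinery end to end:

* the *null* experiment runs the full pipeline on homogeneous landscapes
  (farm type a pure label) and counts the fraction of cluster x indicator
  comparisons significant at alpha — which should match alpha;
* the *recovery* experiment plants a known standardized shift on the
  semi-natural-grassland indicator (Gra) for sheep farms and checks that the
  estimated Cohen's d returns the planted effect.

The recovery experiment evaluates only the Gra column (the planted
indicator): Gra depends just on parcels and the inventory layer, so the
landscape layers that do not enter it are generated at minimal intensity to
keep many-seed runs cheap. Group size means *included* farms per group; the
generated count is inflated by the expected selection-filter exclusion rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparison import compare_scheme
from .config import AnalysisConfig
from .clustering import group_by_type
from .indicators import gra, zscale
from .pipeline import analyse_bundle
from .registry import Farm, StudyArea, select_farms
from .synthetic import (
    LandscapeBundle,
    PlantedEffect,
    SimulationConfig,
    apply_planted_effects,
    simulate,
)


def null_comparison_experiment(
    n_farms: int = 500,
    n_seeds: int = 50,
    base_seed: int = 0,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Full-pipeline comparisons on homogeneous (null) landscapes.

    Returns the concatenated comparison tables over all seeds; the fraction
    of rows with ``significant`` True estimates the realised type-I error at
    the configured alpha.
    """
    cfg = cfg or AnalysisConfig()
    tables = []
    for k in range(n_seeds):
        bundle = simulate(SimulationConfig.homogeneous(n_farms, seed=base_seed + k))
        res = analyse_bundle(bundle, cfg)
        for table in res["comparisons"].values():
            t = table[table["p"].notna()].copy()
            t["seed"] = base_seed + k
            tables.append(t)
    return pd.concat(tables, ignore_index=True)


def _farm_centre(farm: Farm) -> tuple[float, float]:
    areas = np.array([p.geometry.area for p in farm.parcels])
    cents = np.array(
        [[p.geometry.centroid.x, p.geometry.centroid.y] for p in farm.parcels]
    )
    cx, cy = (cents * areas[:, None]).sum(axis=0) / areas.sum()
    return float(cx), float(cy)


def _gra_comparison(bundle: LandscapeBundle, cfg: AnalysisConfig) -> pd.DataFrame:
    """type-scheme comparison table for the Gra column only."""
    included, _ = select_farms(bundle.farms(cfg), cfg)
    inv = bundle.inventory_union()
    col = pd.Series(
        {f.farm_id: gra(f, inv) for f in included}, name="Gra"
    )
    scaled = pd.DataFrame({"Gra": zscale(col.to_numpy(float))}, index=col.index)
    study_areas = {
        f.farm_id: StudyArea(f.farm_id, None, f.agricultural_area_ha, _farm_centre(f))
        for f in included
    }
    areas_ha = {f.farm_id: f.agricultural_area_ha for f in included}
    assignment = group_by_type(included, "detailed")
    table, _ = compare_scheme(
        assignment, scaled, study_areas, areas_ha, cfg, ["Gra"]
    )
    return table


def _recovery_config(n_per_group: int, seed: int) -> SimulationConfig:
    # inflate the generated count by the expected no-cropland exclusion rate
    # so the *included* group sizes match n_per_group
    include_rate = 0.94
    sim = SimulationConfig.homogeneous(
        n_farms=int(round(2 * n_per_group / include_rate)),
        seed=seed,
        mixture={"sheep": 0.5, "crop_production": 0.5},
        grassland_prob=0.25,
    )
    # sparser world than the null default: with ~400 farms per group, group
    # means average over many farms and residual dependence from overlapping
    # 20-km reference sets would otherwise dominate the d estimate's spread;
    # near-constant parcel counts keep the area weights even, which maximises
    # the effective number of references per disc (the reference-mean noise
    # that would otherwise attenuate d through the D-value spread)
    sim.extent_m = float(np.sqrt(sim.n_farms / 0.028) * 1000.0)
    for params in sim.types.values():
        params.parcel_count = (2, 4)
    for params in sim.types.values():
        # every farm keeps ruminants so the pasture-without-ruminants filter
        # cannot interact with planted grassland (selection stays independent
        # of the plant); identical across both groups, so still null
        params.livestock_options = [(1.0, [("sheep", 2.0, 0.4)])]
    # crop sequences do not enter Gra; keep them complete so the coverage
    # filter cannot re-select farms when a parcel is split by the plant
    sim.incomplete_parcel_prob = 0.0
    sim.missing_year_prob = 0.0
    sim.missing_geometry_prob = 0.0
    # layers that do not enter Gra are generated at minimal intensity
    sim.visitor_intensity_per_km2 = {"photo": 0.0, "species_observation": 0.0}
    sim.habitats_per_cropland_ha = 0.0
    sim.road_density_m_per_km2 = 0.0
    sim.pop_cell_m = 5_000.0
    sim.matrix_seeds_per_km2 = 0.02
    return sim


@dataclass
class RecoveryTrial:
    seed: int
    n_sheep: int
    n_reference: int
    d_planted: float
    d_null: float


def gra_recovery_trial(
    n_per_group: int = 400,
    delta: float = 1.0,
    seed: int = 0,
    cfg: AnalysisConfig | None = None,
) -> RecoveryTrial:
    """One planted-vs-null recovery trial.

    Simulates a two-type homogeneous world (sheep vs crop production), plants
    *delta* residual SDs on Gra for sheep farms, and returns the estimated
    Cohen's d for the planted bundle and for the untouched (null) bundle.
    """
    cfg = cfg or AnalysisConfig()
    bundle = simulate(_recovery_config(n_per_group, seed))
    planted = apply_planted_effects(
        bundle, [PlantedEffect("type:sheep", "Gra", delta)], seed=seed
    )
    t_null = _gra_comparison(bundle, cfg)
    t_plant = _gra_comparison(planted, cfg)

    def _d(table: pd.DataFrame) -> float:
        row = table[(table["cluster"] == "sheep") & (table["indicator"] == "Gra")]
        return float(row["cohens_d"].iloc[0])

    n_sheep = int(
        t_plant[(t_plant["cluster"] == "sheep") & (t_plant["indicator"] == "Gra")][
            "n_focal"
        ].iloc[0]
    )
    n_ref = int(
        t_plant[
            (t_plant["cluster"] == "crop_production")
            & (t_plant["indicator"] == "Gra")
        ]["n_focal"].iloc[0]
    )
    return RecoveryTrial(seed, n_sheep, n_ref, _d(t_plant), _d(t_null))


def gra_recovery_experiment(
    n_per_group: int = 400,
    delta: float = 1.0,
    n_seeds: int = 20,
    base_seed: int = 0,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run *n_seeds* recovery trials; one row per seed."""
    rows = [
        gra_recovery_trial(n_per_group, delta, base_seed + k, cfg)
        for k in range(n_seeds)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])
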