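"""Indicator redundancy screening, gridded regional summaries and per-land-use
visitor/protection summaries.

Redundant indicators are screened with Spearman rank correlation: within each
connected group of strongly correlated indicators (r_s >= 0.5, significant at
p < 0.01) only the highest-priority member is retained. The default priority
puts LanVar first, so when the cropland-distance and roadside-variation
indicators track landscape variation they are the ones dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPolygon, Polygon

from .config import AnalysisConfig
from .geometry import UserPoint, overlay_area


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with significance and strength labels."""

    r: pd.DataFrame
    p: pd.DataFrame
    strength: pd.DataFrame  # strong | moderate | weak | n.s.


def spearman_matrix(
    scaled: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> CorrelationMatrix:
    """Pairwise-complete Spearman matrix with average-rank ties.

    Pairs with fewer than 3 complete observations, or p >= alpha, are marked
    not significant. Strength: strong r_s >= 0.5, moderate >= 0.3 (positive,
    significant), else weak; insignificant entries are 'n.s.'.
    """
    cfg = cfg or AnalysisConfig()
    cols = list(scaled.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = scaled[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rs, pv = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rs
            p[i, j] = p[j, i] = pv
    strength = np.full((k, k), "n.s.", dtype=object)
    for i in range(k):
        strength[i, i] = "strong"
        for j in range(k):
            if i == j or not np.isfinite(p[i, j]) or p[i, j] >= cfg.alpha:
                continue
            if r[i, j] >= cfg.strong_correlation:
                strength[i, j] = "strong"
            elif r[i, j] >= cfg.moderate_correlation:
                strength[i, j] = "moderate"
            else:
                strength[i, j] = "weak"
    idx = pd.Index(cols)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        strength=pd.DataFrame(strength, index=idx, columns=idx),
    )


def exclusion_screen(
    corr: CorrelationMatrix,
    priority: Sequence[str],
) -> list[str]:
    """Retained indicator list after dropping redundant ones.

    Strong significant pairs define an undirected graph; within each
    connected component only the highest-priority indicator survives. Output
    order follows the input column order; the result is independent of pair
    enumeration order.
    """
    cols = list(corr.r.columns)
    missing = set(cols) - set(priority)
    if missing:
        raise ValueError(f"priority list misses indicators: {sorted(missing)}")
    rank = {name: i for i, name in enumerate(priority)}
    # union-find over strong significant pairs
    parent = {c: c for c in cols}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if corr.strength.loc[a, b] == "strong":
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    components: dict[str, list[str]] = {}
    for c in cols:
        components.setdefault(find(c), []).append(c)
    retained = set()
    for members in components.values():
        retained.add(min(members, key=lambda m: rank[m]))
    return [c for c in cols if c in retained]


@dataclass
class GridCell:
    """One 15 km summary cell: per-indicator area-weighted means and counts of
    indicators above/below the high/low percentile thresholds."""

    origin: tuple[float, float]
    size_m: float
    means: dict[str, float]
    n_farms: int
    farm_area_ha: float
    n_above: int = 0
    n_below: int = 0


def grid_summary(
    scaled: pd.DataFrame,
    centres: Mapping[str, tuple[float, float]],
    areas_ha: Mapping[str, float],
    cell_m: float = 15_000.0,
    hi: float = 0.80,
    lo: float = 0.20,
    origin: tuple[float, float] | None = None,
) -> list[GridCell]:
    """Area-weighted per-cell indicator means plus percentile hotspot counts.

    Farms are binned by centre point into square cells anchored at *origin*
    (default: lower-left of the farm-centre bounding box). Percentile
    thresholds are computed per indicator over the cell values (inclusive
    linear interpolation); counts use strict inequalities. Empty cells are
    omitted.
    """
    ids = list(scaled.index)
    xy = np.array([centres[f] for f in ids])
    if origin is None:
        origin = (float(xy[:, 0].min()), float(xy[:, 1].min()))
    ij = np.floor((xy - np.asarray(origin)) / cell_m).astype(int)
    cells: dict[tuple[int, int], list[int]] = {}
    for row, key in enumerate(map(tuple, ij)):
        cells.setdefault(key, []).append(row)
    vals = scaled.to_numpy(float)
    w = np.array([areas_ha[f] for f in ids], dtype=float)
    out: list[GridCell] = []
    for key in sorted(cells):
        rows = cells[key]
        sub = vals[rows]
        ws = w[rows]
        mask = ~np.isnan(sub)
        wsum = (ws[:, None] * mask).sum(axis=0)
        num = np.nansum(sub * ws[:, None], axis=0)
        with np.errstate(invalid="ignore"):
            means = np.where(wsum > 0, num / wsum, np.nan)
        out.append(
            GridCell(
                origin=(origin[0] + key[0] * cell_m, origin[1] + key[1] * cell_m),
                size_m=cell_m,
                means=dict(zip(scaled.columns, means.tolist())),
                n_farms=len(rows),
                farm_area_ha=float(ws.sum()),
            )
        )
    # percentile thresholds over cell values, per indicator
    for ind in scaled.columns:
        cell_vals = np.array([c.means[ind] for c in out])
        ok = cell_vals[~np.isnan(cell_vals)]
        if ok.size == 0:
            continue
        hi_thr = float(np.quantile(ok, hi))
        lo_thr = float(np.quantile(ok, lo))
        for c in out:
            v = c.means[ind]
            if np.isnan(v):
                continue
            if v > hi_thr:
                c.n_above += 1
            if v < lo_thr:
                c.n_below += 1
    return out


def plot_grid_summary(
    cells: Sequence[GridCell],
    indicator: str,
    ax=None,
    cmap: str = "RdYlGn",
):
    """Plot one indicator's per-cell area-weighted means as coloured squares.

    A minimal cartographic helper for eyeballing regional patterns; returns
    the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots()
    vals = [c.means.get(indicator, float("nan")) for c in cells]
    finite = [v for v in vals if np.isfinite(v)]
    if not finite:
        raise ValueError(f"no finite cell values for {indicator!r}")
    vmin, vmax = min(finite), max(finite)
    span = (vmax - vmin) or 1.0
    cmap_obj = plt.get_cmap(cmap)
    for cell, v in zip(cells, vals):
        if not np.isfinite(v):
            continue
        ax.add_patch(
            Rectangle(
                cell.origin,
                cell.size_m,
                cell.size_m,
                facecolor=cmap_obj((v - vmin) / span),
                edgecolor="0.7",
                linewidth=0.3,
            )
        )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_title(indicator)
    return ax


def landuse_point_density(
    points: Sequence[UserPoint],
    landuse: Mapping[str, Polygon | MultiPolygon],
) -> pd.DataFrame:
    """Distinct users per km2 per land-use class and source, plus the
    all-class average row (labelled 'all')."""
    from shapely.strtree import STRtree

    rows = []
    tree = STRtree([p.location for p in points]) if points else None
    total_area = 0.0
    total_users = {"photo": set(), "species_observation": set()}
    for cls in sorted(landuse):
        geom = landuse[cls]
        km2 = geom.area / 1e6 if geom is not None and not geom.is_empty else 0.0
        users = {"photo": set(), "species_observation": set()}
        if tree is not None and km2 > 0:
            for i in tree.query(geom, predicate="covers"):
                users[points[i].source].add(points[i].user_id)
        rows.append(
            {
                "land_use": cls,
                "area_km2": km2,
                "photo_users_per_km2": len(users["photo"]) / km2 if km2 else float("nan"),
                "obs_users_per_km2": len(users["species_observation"]) / km2
                if km2
                else float("nan"),
            }
        )
        total_area += km2
        for s in total_users:
            total_users[s] |= users[s]
    rows.append(
        {
            "land_use": "all",
            "area_km2": total_area,
            "photo_users_per_km2": len(total_users["photo"]) / total_area
            if total_area
            else float("nan"),
            "obs_users_per_km2": len(total_users["species_observation"]) / total_area
            if total_area
            else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def landuse_protection_share(
    landuse: Mapping[str, Polygon | MultiPolygon],
    protected_layers: Mapping[str, Polygon | MultiPolygon],
) -> pd.DataFrame:
    """Percentage of each land-use class inside each protected layer."""
    rows = []
    for cls in sorted(landuse):
        geom = landuse[cls]
        area = geom.area if geom is not None and not geom.is_empty else 0.0
        row = {"land_use": cls}
        for layer in sorted(protected_layers):
            if area <= 0:
                row[layer] = float("nan")
            else:
                row[layer] = 100.0 * overlay_area(geom, protected_layers[layer]) / area
        rows.append(row)
    return pd.DataFrame(rows)
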