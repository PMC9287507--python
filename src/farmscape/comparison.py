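"""Local reference comparison: per-farm area-weighted difference and cluster
tests.

Regional conditions (soils, climate, demography) induce spatial
autocorrelation in the indicators. To control for it, each farm is compared
with reference farms within a 20 km radius of its centre point: the
difference D is the farm's scaled indicator value minus the agricultural-
area-weighted mean of the surrounding reference farms,

    D = I - sum(i * a) / sum(a).

Cluster-level differences in mean D are tested with Welch's unequal-variance
t test (alpha = 0.01) and sized with Cohen's d using a variance term
mirroring Welch's (mean of the two sample variances), categorised as large
(|d| > 0.8), moderate (> 0.5), small (> 0.2) or negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .clustering import ClusterAssignment
from .config import AnalysisConfig
from .registry import StudyArea


class DegenerateSampleError(ValueError):
    """Both samples have zero variance; the Welch statistic is undefined."""


@dataclass
class ReferenceContext:
    """Reference farms surrounding one focal farm."""

    focal_id: str
    radius_m: float
    reference_ids: list[str]
    values: np.ndarray  # scaled indicator values i of the references
    areas: np.ndarray  # agricultural areas a (ha)


def local_difference(focal_value: float, ctx: ReferenceContext) -> float:
    """D = I - area-weighted mean of reference values; NaN-safe weights."""
    if len(ctx.reference_ids) == 0:
        return float("nan")
    mask = ~np.isnan(ctx.values)
    if not mask.any():
        return float("nan")
    w = ctx.areas[mask]
    return float(focal_value - (ctx.values[mask] * w).sum() / w.sum())


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variances t statistic, Welch-Satterthwaite df and
    two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least two observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateSampleError("both sample variances are zero")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cohens_d_welch(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the Welch-mirrored variance term: the standardiser is
    the root of the unweighted mean of the two sample variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateSampleError("both sample variances are zero")
    return float((x.mean() - y.mean()) / math.sqrt((vx + vy) / 2.0))


def effect_category(d: float) -> str:
    """Strict |d| thresholds: > 0.8 large, > 0.5 moderate, > 0.2 small."""
    if not math.isfinite(d):
        raise ValueError("effect size must be finite")
    a = abs(d)
    if a > 0.8:
        return "large"
    if a > 0.5:
        return "moderate"
    if a > 0.2:
        return "small"
    return "negligible"


def build_reference_contexts(
    farm_ids: Sequence[str],
    centres: Mapping[str, tuple[float, float]],
    areas_ha: Mapping[str, float],
    scaled_column: Mapping[str, float],
    reference_ids: Sequence[str],
    radius_m: float,
) -> dict[str, ReferenceContext]:
    """Per-focal-farm reference context for one indicator column.

    References are reference-cluster farms within *radius_m* of the focal
    centre (planar centre-to-centre distance); a focal farm that is itself a
    reference never appears in its own context.
    """
    ref_ids = [r for r in reference_ids if r in centres]
    ref_xy = np.array([centres[r] for r in ref_ids])
    ref_vals = np.array([scaled_column[r] for r in ref_ids], dtype=float)
    ref_areas = np.array([areas_ha[r] for r in ref_ids], dtype=float)
    tree = cKDTree(ref_xy) if len(ref_ids) else None
    out: dict[str, ReferenceContext] = {}
    for fid in farm_ids:
        if tree is None:
            out[fid] = ReferenceContext(fid, radius_m, [], np.array([]), np.array([]))
            continue
        idx = tree.query_ball_point(centres[fid], radius_m)
        idx = [i for i in idx if ref_ids[i] != fid]
        out[fid] = ReferenceContext(
            focal_id=fid,
            radius_m=radius_m,
            reference_ids=[ref_ids[i] for i in idx],
            values=ref_vals[idx],
            areas=ref_areas[idx],
        )
    return out


def local_differences(
    scaled: pd.DataFrame,
    centres: Mapping[str, tuple[float, float]],
    areas_ha: Mapping[str, float],
    reference_ids: Sequence[str],
    radius_m: float,
) -> tuple[pd.DataFrame, list[str]]:
    """D matrix (farm x indicator) against one reference set.

    The neighbour search runs once; the weighted mean is vectorised across
    indicator columns. Farms with no reference within the radius get all-NaN
    rows and are reported in the excluded list.
    """
    farm_ids = list(scaled.index)
    ref_ids = [r for r in reference_ids if r in centres]
    ref_xy = np.array([centres[r] for r in ref_ids])
    ref_vals = scaled.loc[ref_ids].to_numpy(float)  # (n_ref, n_ind)
    ref_areas = np.array([areas_ha[r] for r in ref_ids], dtype=float)
    out = np.full((len(farm_ids), scaled.shape[1]), np.nan)
    excluded: list[str] = []
    tree = cKDTree(ref_xy) if ref_ids else None
    pos = {r: i for i, r in enumerate(ref_ids)}
    for row, fid in enumerate(farm_ids):
        if tree is None:
            excluded.append(fid)
            continue
        idx = tree.query_ball_point(centres[fid], radius_m)
        self_pos = pos.get(fid)
        if self_pos is not None and self_pos in idx:
            idx.remove(self_pos)
        if not idx:
            excluded.append(fid)
            continue
        vals = ref_vals[idx]
        w = ref_areas[idx]
        wmask = ~np.isnan(vals)
        wsum = (w[:, None] * wmask).sum(axis=0)
        num = np.nansum(vals * w[:, None], axis=0)
        with np.errstate(invalid="ignore"):
            wmean = np.where(wsum > 0, num / wsum, np.nan)
        out[row] = scaled.loc[fid].to_numpy(float) - wmean
    return pd.DataFrame(out, index=farm_ids, columns=scaled.columns), excluded


def compare_scheme(
    assignment: ClusterAssignment,
    scaled: pd.DataFrame,
    study_areas: Mapping[str, StudyArea],
    areas_ha: Mapping[str, float],
    cfg: AnalysisConfig | None = None,
    indicators: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All cluster x indicator comparisons for one grouping scheme.

    Returns (comparison rows, D matrix). Every farm in the scheme, reference
    farms included, gets a D value per indicator; each non-reference cluster
    is then Welch-tested against the reference cluster's D values. The
    reference cluster's own mean D is reported without a test (area weighting
    makes it deviate from zero). Optional Benjamini-Hochberg correction is
    applied per scheme when configured.
    """
    cfg = cfg or AnalysisConfig()
    cols = list(indicators) if indicators is not None else list(scaled.columns)
    farm_ids = [f for f in scaled.index if f in assignment.labels]
    sub = scaled.loc[farm_ids, cols]
    centres = {fid: study_areas[fid].centre for fid in farm_ids}
    ref_cluster = assignment.cluster_farms(assignment.reference_label)
    ref_cluster = [r for r in ref_cluster if r in sub.index]
    d_matrix, excluded = local_differences(
        sub, centres, areas_ha, ref_cluster, cfg.reference_radius_m
    )
    rows = []
    ref_d = d_matrix.loc[[r for r in ref_cluster if r not in excluded]]
    labels_order = list(assignment.summary["label"])
    for label in labels_order:
        members = [
            f for f in assignment.cluster_farms(label) if f in d_matrix.index
        ]
        for ind in cols:
            dvals = d_matrix.loc[members, ind].dropna().to_numpy()
            refvals = ref_d[ind].dropna().to_numpy()
            row = {
                "scheme": assignment.scheme,
                "cluster": label,
                "indicator": ind,
                "n_focal": int(dvals.size),
                "mean_D": float(dvals.mean()) if dvals.size else float("nan"),
            }
            if label == assignment.reference_label:
                row.update(
                    t=float("nan"), df=float("nan"), p=float("nan"),
                    cohens_d=float("nan"), effect="", significant=False,
                )
            else:
                try:
                    t, df_, p = welch_t(dvals, refvals)
                    d = cohens_d_welch(dvals, refvals)
                    row.update(
                        t=t, df=df_, p=p, cohens_d=d,
                        effect=effect_category(d), significant=bool(p < cfg.alpha),
                    )
                except (ValueError, DegenerateSampleError):
                    row.update(
                        t=float("nan"), df=float("nan"), p=float("nan"),
                        cohens_d=float("nan"), effect="", significant=False,
                    )
            rows.append(row)
    table = pd.DataFrame(rows)
    if cfg.multiple_testing == "benjamini-hochberg":
        mask = table["p"].notna()
        if mask.any():
            from statsmodels.stats.multitest import multipletests

            rej, padj, *_ = multipletests(
                table.loc[mask, "p"], alpha=cfg.alpha, method="fdr_bh"
            )
            table.loc[mask, "p_adjusted"] = padj
            table.loc[mask, "significant"] = rej
    table.attrs["excluded"] = excluded
    return table, d_matrix
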