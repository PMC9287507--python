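"""Farm groupings: type groups, livestock-density clusters, size clusters.

Both clustered variables (LSU/ha and farm area) are scalars, so k-means is
solved *exactly* by dynamic programming over contiguous partitions of the
sorted values — the optimal 1-D partition is always contiguous — instead of
Lloyd/Hartigan-Wong iteration. This removes seed sensitivity: the within-
cluster sum of squares reached is the global optimum of the same objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import LIVESTOCK_CATEGORIES, AnalysisConfig
from .registry import Farm


class SchemeInfeasibleError(RuntimeError):
    """No cluster count satisfies the retention rule for this scheme."""


def _contiguous_cost(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums for interval within-SS of sorted x."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def _interval_ss(s1: np.ndarray, s2: np.ndarray, j: np.ndarray, i: int) -> np.ndarray:
    """Within-SS of sorted x[j..i] inclusive, vectorised over j."""
    cnt = i - j + 1
    tot = s1[i + 1] - s1[j]
    return (s2[i + 1] - s2[j]) - tot * tot / cnt


def kmeans_1d(values: Sequence[float], k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally optimal 1-D k-means.

    Returns (labels, cluster means, within-cluster sum of squares). Labels are
    0..k-1 ordered by increasing cluster mean; deterministic.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1, s2 = _contiguous_cost(xs)
    # D[m, i]: optimal cost of first i+1 points in m+1 clusters
    D = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    idx = np.arange(n)
    D[0, :] = _interval_ss(s1, s2, np.zeros(n, dtype=int), idx[-1]) if n else D[0, :]
    for i in range(n):
        D[0, i] = _interval_ss(s1, s2, np.array([0]), i)[0]
    for m in range(1, k):
        for i in range(m, n):
            j = np.arange(m, i + 1)  # first index of last cluster
            cand = D[m - 1, j - 1] + _interval_ss(s1, s2, j, i)
            best = int(np.argmin(cand))
            D[m, i] = cand[best]
            back[m, i] = j[best]
    # backtrack boundaries
    bounds = []
    i = n - 1
    for m in range(k - 1, 0, -1):
        j = back[m, i]
        bounds.append(j)
        i = j - 1
    bounds = [0] + bounds[::-1] + [n]
    labels_sorted = np.empty(n, dtype=int)
    means = np.empty(k)
    for c in range(k):
        lo, hi = bounds[c], bounds[c + 1]
        labels_sorted[lo:hi] = c
        means[c] = xs[lo:hi].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, means, float(D[k - 1, n - 1])


class KMeans1D:
    """Exact 1-D k-means with a scikit-learn-flavoured surface.

    Attributes after :meth:`fit`: ``labels_``, ``cluster_centers_``,
    ``inertia_`` (within-cluster sum of squares at the global optimum).
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters}

    def set_params(self, **params) -> "KMeans1D":
        for key, val in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, X, y=None) -> "KMeans1D":
        x = np.asarray(X, dtype=float).reshape(-1)
        labels, means, ss = kmeans_1d(x, self.n_clusters)
        self.labels_ = labels
        self.cluster_centers_ = means.reshape(-1, 1)
        self.inertia_ = ss
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X) -> np.ndarray:
        centres = self.cluster_centers_.reshape(-1)
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1)


@dataclass
class ClusterAssignment:
    """One farm grouping: scheme name, farm -> label map, per-cluster summary."""

    scheme: str
    labels: dict[str, str]
    values: dict[str, float]
    summary: pd.DataFrame  # label, mean, lo, hi, n, is_reference
    reference_label: str
    dropped: list[str] = field(default_factory=list)

    def cluster_farms(self, label: str) -> list[str]:
        return sorted(f for f, lab in self.labels.items() if lab == label)

    @property
    def nonreference_labels(self) -> list[str]:
        return [
            lab
            for lab in self.summary["label"]
            if lab != self.reference_label
        ]


def _summarise(
    groups: dict[str, tuple[list[str], list[float]]], reference: str
) -> pd.DataFrame:
    rows = []
    for label, (ids, vals) in groups.items():
        v = np.asarray(vals, dtype=float)
        rows.append(
            {
                "label": label,
                "mean": float(v.mean()) if v.size else float("nan"),
                "lo": float(v.min()) if v.size else float("nan"),
                "hi": float(v.max()) if v.size else float("nan"),
                "n": len(ids),
                "is_reference": label == reference,
            }
        )
    return pd.DataFrame(rows)


def group_by_type(farms: Sequence[Farm], level: str = "detailed") -> ClusterAssignment:
    """One group per farm type; crop production farms are the reference."""
    if level not in ("detailed", "general"):
        raise ValueError("level must be 'detailed' or 'general'")
    reference = "crop_production" if level == "detailed" else "crops"
    labels = {
        f.farm_id: (f.farm_type if level == "detailed" else f.general_type)
        for f in farms
    }
    if reference not in labels.values():
        raise SchemeInfeasibleError(f"no {reference} farms to use as reference")
    values = {f.farm_id: f.agricultural_area_ha for f in farms}
    groups: dict[str, tuple[list[str], list[float]]] = {}
    for f in farms:
        lab = labels[f.farm_id]
        groups.setdefault(lab, ([], []))[0].append(f.farm_id)
        groups[lab][1].append(values[f.farm_id])
    return ClusterAssignment(
        scheme=f"type_{level}",
        labels=labels,
        values=values,
        summary=_summarise(groups, reference),
        reference_label=reference,
    )


def cluster_density(
    farms: Sequence[Farm],
    category: str,
    min_cluster_n: int = 20,
    target_clusters: int = 4,
    k_max: int = 12,
) -> ClusterAssignment:
    """Livestock-density clusters for one livestock category.

    Input farms must keep either no livestock (the zero-LSU reference) or
    only the given category; a mixed-species farm is a precondition
    violation. k is increased from *target_clusters* until k-means on LSU/ha
    yields at least *target_clusters* clusters with more than *min_cluster_n*
    farms each; smaller clusters are dropped (their farms leave the scheme).
    """
    if category not in set(LIVESTOCK_CATEGORIES.values()):
        raise ValueError(f"unknown livestock category {category!r}")
    reference_ids: list[str] = []
    clustered: list[Farm] = []
    for f in farms:
        cats = f.livestock_categories()
        if not cats or f.lsu == 0:
            reference_ids.append(f.farm_id)
        elif cats == {category}:
            clustered.append(f)
        else:
            raise ValueError(
                f"farm {f.farm_id} keeps {sorted(cats)}; only single-"
                f"{category} or zero-livestock farms belong to this scheme"
            )
    dens = np.array([f.lsu_density for f in clustered])
    for k in range(target_clusters, k_max + 1):
        if k > dens.size:
            break
        lab_idx, means, _ = kmeans_1d(dens, k)
        counts = np.bincount(lab_idx, minlength=k)
        qualifying = np.flatnonzero(counts > min_cluster_n)
        if qualifying.size >= target_clusters:
            labels: dict[str, str] = {fid: "ref" for fid in reference_ids}
            values: dict[str, float] = {fid: 0.0 for fid in reference_ids}
            dropped: list[str] = []
            keep_rank = {c: r + 1 for r, c in enumerate(sorted(qualifying))}
            for f, ci, d in zip(clustered, lab_idx, dens):
                if ci in keep_rank:
                    labels[f.farm_id] = f"d{keep_rank[ci]}"
                    values[f.farm_id] = float(d)
                else:
                    dropped.append(f.farm_id)
            groups: dict[str, tuple[list[str], list[float]]] = {}
            for fid, lab in labels.items():
                groups.setdefault(lab, ([], []))[0].append(fid)
                groups[lab][1].append(values[fid])
            return ClusterAssignment(
                scheme=f"density_{category}",
                labels=labels,
                values=values,
                summary=_summarise(groups, "ref"),
                reference_label="ref",
                dropped=sorted(dropped),
            )
    raise SchemeInfeasibleError(
        f"no k in [{target_clusters}, {k_max}] gives >= {target_clusters} "
        f"clusters with > {min_cluster_n} of the {dens.size} single-"
        f"{category} farms"
    )


def cluster_size(farms: Sequence[Farm], k: int = 5) -> ClusterAssignment:
    """Five farm-size clusters on total agricultural area; the most populous
    cluster (normally the smallest sizes) is the reference."""
    sizes = np.array([f.agricultural_area_ha for f in farms])
    if sizes.size < k or np.unique(sizes).size < k:
        raise ValueError(f"need at least {k} farms with distinct sizes")
    lab_idx, means, _ = kmeans_1d(sizes, k)
    counts = np.bincount(lab_idx, minlength=k)
    ref_idx = int(np.argmax(counts))
    if ref_idx != int(np.argmin(means)):
        warnings.warn(
            "most populous size cluster is not the smallest-size cluster; "
            "using it as reference regardless"
        )
    labels = {f.farm_id: f"s{ci + 1}" for f, ci in zip(farms, lab_idx)}
    values = {f.farm_id: float(s) for f, s in zip(farms, sizes)}
    groups: dict[str, tuple[list[str], list[float]]] = {}
    for fid, lab in labels.items():
        groups.setdefault(lab, ([], []))[0].append(fid)
        groups[lab][1].append(values[fid])
    return ClusterAssignment(
        scheme="size",
        labels=labels,
        values=values,
        summary=_summarise(groups, f"s{ref_idx + 1}"),
        reference_label=f"s{ref_idx + 1}",
    )


def build_density_schemes(
    farms: Sequence[Farm], cfg: AnalysisConfig | None = None
) -> dict[str, ClusterAssignment]:
    """All feasible per-category density schemes over the included farms.

    For each livestock category the candidate set is single-category farms of
    that category plus all zero-livestock farms; categories whose retention
    rule cannot be met are skipped.
    """
    cfg = cfg or AnalysisConfig()
    out: dict[str, ClusterAssignment] = {}
    for category in sorted(set(LIVESTOCK_CATEGORIES.values())):
        eligible = [
            f
            for f in farms
            if f.lsu == 0 or f.livestock_categories() == {category}
        ]
        try:
            out[category] = cluster_density(
                eligible,
                category,
                cfg.min_cluster_n,
                cfg.density_target_clusters,
                cfg.density_k_max,
            )
        except SchemeInfeasibleError:
            continue
    return out
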