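"""Exact 1-D k-means and the three farm grouping schemes."""

import itertools

import numpy as np
import pytest
from shapely.geometry import box

from farmscape.clustering import (
    KMeans1D,
    SchemeInfeasibleError,
    cluster_density,
    cluster_size,
    group_by_type,
    kmeans_1d,
)
from farmscape.registry import Parcel, build_farms

SEQ = tuple(["ley"] * 7)


def brute_force_1d(values, k):
    """Optimal contiguous partition of sorted values by exhaustive search."""
    xs = np.sort(np.asarray(values, dtype=float))
    n = xs.size
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        ss = sum(
            ((xs[a:b] - xs[a:b].mean()) ** 2).sum() for a, b in zip(bounds, bounds[1:])
        )
        if ss < best[0] - 1e-12:
            best = (ss, bounds)
    return best[0]


class TestKMeans1D:
    def test_two_obvious_groups(self):
        labels, means, ss = kmeans_1d([0, 0, 0, 10, 10, 10], 2)
        assert sorted(means) == [0.0, 10.0]
        assert ss == pytest.approx(0.0)

    def test_three_groups_exhaustive_values(self):
        _, means, _ = kmeans_1d([1, 2, 3, 10, 11, 12, 30], 3)
        assert sorted(means) == pytest.approx([2.0, 11.0, 30.0])

    def test_k_equals_one_is_grand_mean(self):
        _, means, ss = kmeans_1d([1.0, 4.0, 7.0], 1)
        assert means[0] == pytest.approx(4.0)
        assert ss == pytest.approx(18.0)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_1d([1.0, 2.0], 3)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_partition_search(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(2, min(n, 5)))
        x = rng.uniform(0, 100, n)
        _, _, ss = kmeans_1d(x, k)
        assert ss == pytest.approx(brute_force_1d(x, k), rel=1e-9, abs=1e-9)

    def test_labels_ordered_by_mean_and_contiguous(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        labels, means, _ = kmeans_1d(x, 4)
        assert np.all(np.diff(means) > 0)
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(labels[order]) >= 0)

    def test_estimator_surface(self):
        est = KMeans1D(n_clusters=2).fit([0.0, 0.1, 9.9, 10.0])
        assert sorted(est.labels_) == [0, 0, 1, 1]
        assert est.get_params() == {"n_clusters": 2}
        assert est.set_params(n_clusters=3).n_clusters == 3
        assert list(est.predict([0.05])) == [0]


def _farm(fid, area_ha, counts=None, ftype_hours=None, grassland=False):
    side = float(np.sqrt(area_ha * 1e4))
    x0 = hash(fid) % 1000 * 2000.0
    parcels = [Parcel(f"p{fid}", fid, box(x0, 0, x0 + side, side), "cropland", SEQ)]
    if grassland:
        parcels.append(
            Parcel(f"g{fid}", fid, box(x0 + side + 100, 0, x0 + side + 200, 100),
                   "semi_natural_grassland")
        )
    rec = {
        "farm_id": fid,
        "hours": ftype_hours or {"crops": 1000.0},
        "counts": counts or {},
    }
    return build_farms([rec], parcels)[0]


class TestClusterDensity:
    def _farms_with_modes(self, per_mode=25):
        farms = []
        rng = np.random.default_rng(0)
        k = 0
        for mode in (0.2, 0.6, 1.2, 2.5):
            for _ in range(per_mode):
                area = 10.0
                heads = max(1, int(round(mode * area / 0.6 + rng.normal(0, 0.5))))
                farms.append(_farm(f"c{k:03d}", area, {"other_cattle": heads}))
                k += 1
        for i in range(30):  # zero-livestock reference
            farms.append(_farm(f"z{i:03d}", 10.0))
        return farms

    def test_recovers_well_separated_modes(self):
        a = cluster_density(self._farms_with_modes(), "cattle")
        retained = [l for l in a.summary["label"] if l != "ref"]
        assert len(retained) == 4
        means = sorted(a.summary[a.summary["label"] != "ref"]["mean"])
        assert means == pytest.approx([0.2, 0.6, 1.2, 2.5], abs=0.15)

    def test_small_extreme_cluster_dropped(self):
        farms = self._farms_with_modes()
        for i in range(3):  # 3 extreme-density outliers form a tiny cluster
            farms.append(_farm(f"x{i}", 10.0, {"other_cattle": 200}))
        a = cluster_density(farms, "cattle")
        assert len(a.dropped) == 3
        retained = [l for l in a.summary["label"] if l != "ref"]
        assert len(retained) == 4

    def test_drop_does_not_change_other_memberships(self):
        base = self._farms_with_modes()
        extended = base + [_farm(f"x{i}", 10.0, {"other_cattle": 200}) for i in range(3)]
        a = cluster_density(base, "cattle")
        b = cluster_density(extended, "cattle")
        kept = {f for f in b.labels if not f.startswith("x")}
        assert {f: a.labels[f] for f in a.labels} == {f: b.labels[f] for f in kept}

    def test_mixed_species_farm_rejected(self):
        farms = self._farms_with_modes()
        farms.append(_farm("mix", 10.0, {"other_cattle": 5, "pig": 20}))
        with pytest.raises(ValueError, match="mix"):
            cluster_density(farms, "cattle")

    def test_infeasible_scheme_raises(self):
        farms = [_farm(f"c{i}", 10.0, {"other_cattle": 6}) for i in range(10)]
        with pytest.raises(SchemeInfeasibleError):
            cluster_density(farms, "cattle")

    def test_cluster_bounds_disjoint_and_ordered(self):
        a = cluster_density(self._farms_with_modes(), "cattle")
        sub = a.summary[a.summary["label"] != "ref"].sort_values("mean")
        his = sub["hi"].to_numpy()
        los = sub["lo"].to_numpy()
        assert np.all(los[1:] > his[:-1])


class TestClusterSize:
    def test_most_populous_cluster_is_reference_and_smallest(self):
        rng = np.random.default_rng(1)
        farms = [
            _farm(f"s{i:03d}", float(np.exp(rng.normal(np.log(15), 0.8))))
            for i in range(150)
        ]
        a = cluster_size(farms, 5)
        summary = a.summary
        ref_row = summary[summary["is_reference"]].iloc[0]
        assert ref_row["n"] == summary["n"].max()
        assert ref_row["mean"] == summary["mean"].min()

    def test_identical_sizes_rejected(self):
        farms = [_farm(f"e{i}", 10.0) for i in range(5)]
        with pytest.raises(ValueError):
            cluster_size(farms, 5)

    def test_label_invariance_to_input_order(self):
        rng = np.random.default_rng(2)
        farms = [_farm(f"s{i:03d}", float(rng.uniform(2, 200))) for i in range(40)]
        a = cluster_size(farms, 5)
        b = cluster_size(farms[::-1], 5)
        assert a.labels == b.labels


class TestGroupByType:
    def test_partition_covers_all_and_reference(self):
        farms = [
            _farm("a", 10.0, ftype_hours={"crops": 1000}),
            _farm("b", 10.0, ftype_hours={"dairy": 1000}),
            _farm("c", 10.0, ftype_hours={"crops": 100}),
        ]
        a = group_by_type(farms, "detailed")
        assert set(a.labels) == {"a", "b", "c"}
        assert a.reference_label == "crop_production"
        assert a.labels["c"] == "small_scale"

    def test_general_level_merges_ruminants(self):
        farms = [
            _farm("a", 10.0, ftype_hours={"crops": 1000}),
            _farm("b", 10.0, ftype_hours={"dairy": 1000}),
            _farm("c", 10.0, ftype_hours={"sheep": 1000}),
        ]
        a = group_by_type(farms, "general")
        assert a.labels["b"] == a.labels["c"] == "ruminants"

    def test_missing_reference_raises(self):
        farms = [_farm("b", 10.0, ftype_hours={"dairy": 1000})]
        with pytest.raises(SchemeInfeasibleError):
            group_by_type(farms, "detailed")
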