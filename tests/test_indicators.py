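"""Indicator definitions: worked examples, composites and scaling."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, box

from farmscape.config import ConfigError, CropConfig
from farmscape.geometry import LandCoverPatch, UserPoint, buffer_region
from farmscape.indicators import (
    SmallScaleHabitat,
    acc_components,
    crpseq_farm,
    crpseq_parcel,
    gra,
    lanvar,
    natres,
    rodvar,
    scale_matrix,
    sshab,
    visit_components,
    zscale,
)
from farmscape.registry import Parcel, StudyArea, build_farms

SEQ = tuple(["ley"] * 7)


def _farm(parcels):
    recs = [{"farm_id": "F", "hours": {"crops": 1000.0}, "counts": {"sheep": 5}}]
    return build_farms(recs, parcels)[0]


def _study(geom):
    return StudyArea("F", geom, geom.area / 1e4, (geom.centroid.x, geom.centroid.y))


class TestLanVar:
    def test_two_patches_ratio(self):
        mosaic = [
            LandCoverPatch(box(0, 0, 1, 1), "cropland", "a"),
            LandCoverPatch(box(1, 0, 2, 1), "forest", "b"),
        ]
        study = _study(box(0, 0, 2, 1))  # 2 m2 = 2e-4 ha
        assert lanvar(study, mosaic) == pytest.approx(5000.0)

    def test_homogeneous_window_is_zero(self):
        mosaic = [LandCoverPatch(box(0, 0, 2, 1), "cropland", "a")]
        assert lanvar(_study(box(0, 0, 2, 1)), mosaic) == 0.0

    def test_larger_area_without_new_borders_halves_value(self):
        mosaic = [
            LandCoverPatch(box(0, 0, 1, 1), "cropland", "a"),
            LandCoverPatch(box(1, 0, 2, 1), "forest", "b"),
            LandCoverPatch(box(2, 0, 4, 1), "forest", "c2"),
        ]
        small = lanvar(_study(box(0, 0, 2, 1)), mosaic)
        # forest|forest edge adds nothing; doubling the window halves LanVar
        big = lanvar(_study(box(0, 0, 4, 1)), mosaic)
        assert big == pytest.approx(small / 2)


class TestGra:
    def test_factor_of_two_on_inventory_overlap(self):
        # 3 ha grassland of which 1 ha in the inventory, 10 ha farm
        farm = _farm([
            Parcel("c", "F", box(0, 0, 700, 100), "cropland", SEQ),
            Parcel("g", "F", box(800, 0, 1100, 100), "semi_natural_grassland"),
        ])
        inventory = box(800, 0, 900, 100)  # 1 ha inside the grassland
        assert gra(farm, inventory) == pytest.approx((3 + 1) / 10)

    def test_no_grassland(self):
        farm = _farm([Parcel("c", "F", box(0, 0, 100, 1000), "cropland", SEQ)])
        assert gra(farm, box(0, 0, 10, 10)) == 0.0

    def test_full_inventory_doubles(self):
        farm = _farm([
            Parcel("c", "F", box(0, 0, 700, 100), "cropland", SEQ),
            Parcel("g", "F", box(800, 0, 1100, 100), "semi_natural_grassland"),
        ])
        assert gra(farm, box(800, 0, 1100, 100)) == pytest.approx(0.6)


class TestSSHab:
    def test_count_per_hectare(self):
        farm = _farm([Parcel("c", "F", box(0, 0, 100, 200), "cropland", SEQ)])  # 2 ha
        habitats = [SmallScaleHabitat(Point(10 + i, 10), "field_islet") for i in range(4)]
        assert sshab(habitats, farm) == pytest.approx(2.0)

    def test_outside_points_not_counted(self):
        farm = _farm([Parcel("c", "F", box(0, 0, 100, 200), "cropland", SEQ)])
        habitats = [SmallScaleHabitat(Point(500, 500), "field_islet")]
        assert sshab(habitats, farm) == 0.0

    def test_zero_cropland_is_undefined(self):
        farm = _farm([Parcel("g", "F", box(0, 0, 100, 100), "semi_natural_grassland")])
        assert math.isnan(sshab([SmallScaleHabitat(Point(1, 1), "x")] * 3, farm))


class TestCrpSeq:
    def test_all_ley_hand_value(self):
        cfg = CropConfig()
        # 0.5*1 (ley|ley succession) + 0.3*1 (R=0 always met) + 0.2*0 (one crop)
        assert crpseq_parcel(["ley"] * 7, cfg) == pytest.approx(0.80)

    def test_wheat_monoculture_hand_value(self):
        cfg = CropConfig()
        assert cfg.s("winter_wheat", "winter_wheat") == 0.2
        assert cfg.r("winter_wheat") == 2
        # 0.5*0.2 + 0.3*0 (gap 1 < 2 every year) + 0.2*0
        assert crpseq_parcel(["winter_wheat"] * 7, cfg) == pytest.approx(0.10)

    def test_seven_distinct_compliant_crops(self):
        cfg = CropConfig()
        seq = list(cfg.crops)  # 7 distinct codes
        pair = np.mean([cfg.s(a, b) for a, b in zip(seq, seq[1:])])
        expected = 0.5 * pair + 0.3 * 1.0 + 0.2 * 1.0
        assert crpseq_parcel(seq, cfg) == pytest.approx(expected)

    def test_ley_rich_diverse_beats_monoculture(self):
        cfg = CropConfig()
        diverse = ["ley", "ley", "winter_wheat", "ley", "oats", "ley", "ley"]
        assert crpseq_parcel(diverse, cfg) > crpseq_parcel(["winter_wheat"] * 7, cfg)

    def test_unknown_crop_code_rejected(self):
        with pytest.raises(ConfigError):
            crpseq_parcel(["maize"] * 7, CropConfig())

    def test_farm_area_weighting(self):
        p1 = Parcel("a", "F", box(0, 0, 100, 100), "cropland", SEQ)  # 1 ha, 0.8
        wheat = tuple(["winter_wheat"] * 7)
        p2 = Parcel("b", "F", box(200, 0, 300, 300), "cropland", wheat)  # 3 ha, 0.1
        farm = _farm([p1, p2])
        assert crpseq_farm(farm, CropConfig()) == pytest.approx(
            (1 * 0.8 + 3 * 0.1) / 4
        )

    def test_low_coverage_is_undefined(self):
        p1 = Parcel("a", "F", box(0, 0, 100, 100), "cropland", SEQ)
        p2 = Parcel("b", "F", box(200, 0, 300, 300), "cropland", (None,) * 7)
        farm = _farm([p1, p2])  # complete coverage 25% < 50%
        assert math.isnan(crpseq_farm(farm, CropConfig()))


class TestRodVar:
    def test_road_crossing_two_of_three_patches(self):
        mosaic = [
            LandCoverPatch(box(0, 0, 40, 100), "cropland", "a"),
            LandCoverPatch(box(40, 0, 80, 100), "forest", "b"),
            LandCoverPatch(box(80, 0, 100, 100), "water", "c"),
        ]
        study = _study(box(0, 0, 100, 100))  # 1 ha
        zone = buffer_region([LineString([(-10, 50), (60, 50)])], 5.0)
        assert rodvar(mosaic, zone, study) == pytest.approx(2.0)

    def test_no_roads(self):
        mosaic = [LandCoverPatch(box(0, 0, 100, 100), "cropland", "a")]
        assert rodvar(mosaic, None, _study(box(0, 0, 100, 100))) == 0.0

    def test_patch_touched_by_two_roads_counted_once(self):
        mosaic = [LandCoverPatch(box(0, 0, 100, 100), "cropland", "a")]
        zone = buffer_region(
            [LineString([(0, 20), (100, 20)]), LineString([(0, 80), (100, 80)])], 5.0
        )
        study = _study(box(0, 0, 100, 100))
        assert rodvar(mosaic, zone, study) == pytest.approx(1.0)


class TestAccComponents:
    def test_central_road_share(self):
        study = _study(box(0, 0, 1000, 1000))
        zone = buffer_region([LineString([(-300, 500), (1300, 500)])], 100.0)
        cells = [box(0, 0, 1000, 1000)]
        share, dens = acc_components(study, zone, cells, [100.0])
        assert share == pytest.approx(0.2, rel=1e-6)
        assert dens == pytest.approx(100.0)

    def test_no_roads_zero_share(self):
        study = _study(box(0, 0, 1000, 1000))
        share, _ = acc_components(study, None, [box(0, 0, 1000, 1000)], [50.0])
        assert share == 0.0

    def test_uniform_raster_mean(self):
        study = _study(box(0, 0, 500, 500))
        cells = [box(i * 1000, j * 1000, (i + 1) * 1000, (j + 1) * 1000)
                 for i in range(3) for j in range(3)]
        _, dens = acc_components(study, None, cells, [42.0] * 9)
        assert dens == pytest.approx(42.0)


class TestVisitComponents:
    def test_distinct_users_per_km2(self):
        study = _study(box(0, 0, 2000, 1000))  # 2 km2
        pts = (
            [UserPoint(Point(10 * i + 5, 5), f"p{i % 3}", "photo") for i in range(5)]
            + [UserPoint(Point(500, 500), "o1", "species_observation")]
            + [UserPoint(Point(600, 500), "o2", "species_observation")]
        )
        photo, obs = visit_components(pts, study)
        assert photo == pytest.approx(1.5)  # 3 distinct photo users
        assert obs == pytest.approx(1.0)

    def test_repeat_uploads_count_one_user(self):
        study = _study(box(0, 0, 1000, 1000))
        pts = [UserPoint(Point(i + 1, 1), "same", "photo") for i in range(10)]
        photo, _ = visit_components(pts, study)
        assert photo == pytest.approx(1.0)

    def test_no_points(self):
        assert visit_components([], _study(box(0, 0, 1000, 1000))) == (0.0, 0.0)


class TestNatRes:
    def test_per_layer_sum_overlapping_layers_add(self):
        study = _study(box(0, 0, 1000, 100))  # 10 ha
        same = box(0, 0, 200, 100)  # 2 ha, in both layers
        layers = {"nature_reserve": same, "natura2000": same}
        assert natres(layers, study) == pytest.approx(0.4)

    def test_no_overlap(self):
        study = _study(box(0, 0, 100, 100))
        assert natres({"nature_reserve": box(5000, 0, 5100, 100)}, study) == 0.0

    def test_full_containment_single_layer(self):
        study = _study(box(0, 0, 100, 100))
        assert natres({"natura2000": box(-50, -50, 200, 200)}, study) == pytest.approx(1.0)


class TestScaling:
    def test_population_sd_z_scores(self):
        out = zscale(np.array([1.0, 2.0, 3.0]))
        assert out == pytest.approx([-1.22474487, 0.0, 1.22474487])

    def test_constant_column_scales_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            out = zscale(np.array([5.0, 5.0, 5.0]))
        assert out == pytest.approx([0.0, 0.0, 0.0])

    def test_scaled_columns_standardised(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(
            rng.normal(size=(40, 4)),
            columns=["LanVar", "Gra", "SSHab", "CrpSeq"],
        )
        scaled = scale_matrix(raw)
        for col in scaled.columns:
            assert scaled[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert scaled[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_composites_built_from_scaled_components(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(
            {
                "road_share": rng.uniform(0, 1, 30),
                "pop_density": rng.uniform(0, 500, 30),
                "photo_users_per_km2": rng.uniform(0, 5, 30),
                "obs_users_per_km2": rng.uniform(0, 5, 30),
            }
        )
        raw["Acc"] = 0.0
        raw["Visit"] = 0.0
        scaled = scale_matrix(raw)
        acc = zscale(raw["road_share"].to_numpy()) + zscale(
            raw["pop_density"].to_numpy()
        )
        assert scaled["Acc"].to_numpy() == pytest.approx(zscale(acc))

    def test_missing_entries_ignored(self):
        vals = np.array([1.0, np.nan, 3.0, 5.0])
        out = zscale(vals)
        assert math.isnan(out[1])
        assert np.nanmean(out) == pytest.approx(0.0, abs=1e-12)


class TestRigidMotionInvariance:
    def test_lanvar_invariant_under_rotation(self):
        from shapely.affinity import rotate

        mosaic = [
            LandCoverPatch(box(0, 0, 30, 20), "cropland", "a"),
            LandCoverPatch(box(30, 0, 60, 20), "forest", "b"),
        ]
        window = box(0, 0, 60, 20)
        base = lanvar(_study(window), mosaic)
        rot = [
            LandCoverPatch(rotate(p.geometry, 31.0, origin=(0, 0)), p.patch_class, p.patch_id)
            for p in mosaic
        ]
        moved = lanvar(_study(rotate(window, 31.0, origin=(0, 0))), rot)
        assert moved == pytest.approx(base, rel=1e-9)
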