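"""Synthetic landscape generator: determinism, structure, round-trips and
planted effects."""

import filecmp
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import farmscape as fs
from farmscape.synthetic import (
    SimulationConfigError,
    config_from_dict,
    config_to_dict,
)


def _cfg(**kw):
    base = dict(n_farms=40, extent_m=20_000.0, seed=3)
    base.update(kw)
    return fs.SimulationConfig(**base)


class TestSimulate:
    def test_deterministic_given_seed(self, tmp_path):
        a = fs.simulate(_cfg())
        b = fs.simulate(_cfg())
        da, db = tmp_path / "a", tmp_path / "b"
        fs.write_bundle(a, da)
        fs.write_bundle(b, db)
        for f in sorted(p.name for p in da.iterdir()):
            assert filecmp.cmp(da / f, db / f, shallow=False), f

    def test_distinct_seeds_differ(self):
        a = fs.simulate(_cfg(seed=1))
        b = fs.simulate(_cfg(seed=2))
        pa = {(p.location.x, p.location.y) for p in a.visitor_points}
        pb = {(p.location.x, p.location.y) for p in b.visitor_points}
        assert pa != pb

    def test_farm_count_as_configured(self):
        assert len(fs.simulate(_cfg()).records) == 40

    def test_zero_visitor_intensity(self):
        cfg = _cfg()
        cfg.visitor_intensity_per_km2 = {"photo": 0.0, "species_observation": 0.0}
        assert fs.simulate(cfg).visitor_points == []

    def test_zero_farms_rejected(self):
        with pytest.raises(SimulationConfigError):
            fs.SimulationConfig(n_farms=0)

    def test_bad_mixture_rejected(self):
        cfg = fs.SimulationConfig.homogeneous(10)
        types = {k: v for k, v in cfg.types.items()}
        types["crop_production"].proportion += 0.5
        with pytest.raises(SimulationConfigError):
            fs.SimulationConfig(n_farms=10, types=types)

    def test_parcels_inside_world_and_sequences_seven_slots(self, small_bundle):
        for p in small_bundle.parcels:
            minx, miny, maxx, maxy = p.geometry.bounds
            assert 0 <= minx and maxx <= small_bundle.extent_m
            assert 0 <= miny and maxy <= small_bundle.extent_m
            if p.land_use == "cropland":
                assert len(p.crop_sequence) == 7

    def test_mosaic_patches_do_not_overlap(self, small_bundle):
        from farmscape.geometry import shared_border_length

        # validation raises on overlap; smoke the full mosaic
        shared_border_length(small_bundle.patches, validate=True)

    def test_type_shares_converge_to_mixture(self):
        cfg = fs.SimulationConfig.homogeneous(n_farms=1500, seed=11)
        cfg.matrix_seeds_per_km2 = 0.0  # only the register matters here
        cfg.visitor_intensity_per_km2 = {"photo": 0.0, "species_observation": 0.0}
        cfg.road_density_m_per_km2 = 0.0
        cfg.habitats_per_cropland_ha = 0.0
        bundle = fs.simulate(cfg)
        counts = Counter(
            fs.classify_farm_type(r["hours"]) for r in bundle.records
        )
        for name, params in cfg.types.items():
            se = np.sqrt(params.proportion * (1 - params.proportion) / 1500)
            assert abs(counts[name] / 1500 - params.proportion) < 4 * se + 1e-9

    def test_register_types_match_generated_hours_profiles(self, small_bundle):
        farms = small_bundle.farms()
        names = {f.farm_type for f in farms}
        assert names <= set(fs.SimulationConfig().types)


class TestRoundTrip:
    def test_write_read_equal(self, small_bundle, tmp_path):
        d1 = tmp_path / "one"
        fs.write_bundle(small_bundle, d1)
        again = fs.read_bundle(d1)
        d2 = tmp_path / "two"
        fs.write_bundle(again, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f

    def test_empty_layers_valid_files(self, tmp_path):
        cfg = _cfg()
        cfg.protected_coverage = {"nature_reserve": 0.0}
        cfg.visitor_intensity_per_km2 = {"photo": 0.0, "species_observation": 0.0}
        bundle = fs.simulate(cfg)
        fs.write_bundle(bundle, tmp_path / "empty")
        again = fs.read_bundle(tmp_path / "empty")
        assert again.protected["nature_reserve"] == []
        assert again.visitor_points == []

    def test_config_dict_round_trip(self):
        cfg = fs.SimulationConfig.homogeneous(77, seed=5)
        assert config_from_dict(config_to_dict(cfg)) == cfg


class TestPlantedEffects:
    def test_unknown_indicator_rejected(self):
        with pytest.raises(ValueError):
            fs.PlantedEffect("type:sheep", "NotAnIndicator", 1.0)

    def test_zero_delta_is_identity(self, small_bundle):
        out = fs.apply_planted_effects(
            small_bundle, [fs.PlantedEffect("type:sheep", "Gra", 0.0)], seed=1
        )
        assert len(out.parcels) == len(small_bundle.parcels)
        a = [p.geometry.area for p in out.parcels]
        b = [p.geometry.area for p in small_bundle.parcels]
        assert a == pytest.approx(b)

    def test_null_plant_leaves_distribution_unchanged(self):
        # distributions across two seeds of the same config differ only by
        # sampling noise; a zero plant must not shift them (two-sample KS)
        cfg = fs.SimulationConfig.homogeneous(300, seed=21, grassland_prob=0.25)
        bundle = fs.simulate(cfg)
        planted = fs.apply_planted_effects(
            bundle, [fs.PlantedEffect("type:sheep", "Gra", 0.0)], seed=2
        )
        inv = bundle.inventory_union()
        from farmscape.indicators import gra

        a = [gra(f, inv) for f in bundle.farms() if f.parcels]
        b = [gra(f, planted.inventory_union()) for f in planted.farms() if f.parcels]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_gra_plant_shifts_group_exactly(self):
        cfg = fs.SimulationConfig.homogeneous(
            300, seed=9, mixture={"sheep": 0.5, "crop_production": 0.5},
            grassland_prob=0.25,
        )
        for params in cfg.types.values():
            params.livestock_options = [(1.0, [("sheep", 2.0, 0.4)])]
        bundle = fs.simulate(cfg)
        delta = 1.0
        planted = fs.apply_planted_effects(
            bundle, [fs.PlantedEffect("type:sheep", "Gra", delta)], seed=1
        )
        from farmscape.indicators import gra
        from farmscape.registry import select_farms

        inc0, _ = select_farms(bundle.farms())
        inv0 = bundle.inventory_union()
        raw0 = {f.farm_id: gra(f, inv0) for f in inc0}
        sigma = np.std(list(raw0.values()))
        inc1, _ = select_farms(planted.farms())
        inv1 = planted.inventory_union()
        raw1 = {f.farm_id: gra(f, inv1) for f in inc1}
        shifts = [
            raw1[f.farm_id] - raw0[f.farm_id]
            for f in inc0
            if f.farm_type == "sheep" and f.farm_id in raw1
        ]
        untouched = [
            raw1[f.farm_id] - raw0[f.farm_id]
            for f in inc0
            if f.farm_type != "sheep" and f.farm_id in raw1
        ]
        assert np.mean(shifts) == pytest.approx(delta * sigma, rel=0.02)
        assert untouched == pytest.approx([0.0] * len(untouched))

    def test_agricultural_area_preserved_by_gra_plant(self):
        cfg = fs.SimulationConfig.homogeneous(
            150, seed=13, mixture={"sheep": 0.5, "crop_production": 0.5},
            grassland_prob=0.25,
        )
        for params in cfg.types.values():
            params.livestock_options = [(1.0, [("sheep", 2.0, 0.4)])]
        bundle = fs.simulate(cfg)
        planted = fs.apply_planted_effects(
            bundle, [fs.PlantedEffect("type:sheep", "Gra", 1.0)], seed=1
        )
        a0 = {f.farm_id: f.agricultural_area_ha for f in bundle.farms()}
        a1 = {f.farm_id: f.agricultural_area_ha for f in planted.farms()}
        for fid in a0:
            assert a1[fid] == pytest.approx(a0[fid], rel=1e-9)

    def test_sshab_plant_adds_points_inside_cropland(self, small_bundle):
        planted = fs.apply_planted_effects(
            small_bundle,
            [fs.PlantedEffect("general:ruminants", "SSHab", 1.0)],
            seed=4,
        )
        assert len(planted.habitats) > len(small_bundle.habitats)

    def test_unknown_group_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            fs.apply_planted_effects(
                small_bundle, [fs.PlantedEffect("flock:alpha", "Gra", 1.0)], seed=1
            )
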