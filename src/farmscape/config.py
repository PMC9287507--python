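"""Analysis configuration: every numeric constant used anywhere in the pipeline.

Defaults follow the study design the package implements: 50 m study-area
buffer, 100 m road distance, 10 km population buffer, 20 km reference radius,
alpha = 0.01, strong-correlation threshold 0.5, minimum density-cluster size
20, five farm-size clusters, 15 km summary grid with 80th/20th percentiles,
seven-year crop sequences with a 50% completeness threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Indicator vocabulary, in canonical column order.
INDICATORS = (
    "LanVar",
    "CrpDst",
    "Gra",
    "SSHab",
    "CrpSeq",
    "RodVar",
    "Acc",
    "Visit",
    "NatRes",
)

#: Eurostat-style livestock-unit coefficients (config-overridable).
DEFAULT_LSU_TABLE = {
    "dairy_cow": 1.0,
    "other_cattle": 0.6,
    "sheep": 0.1,
    "horse": 0.8,
    "pig": 0.3,
    "poultry": 0.014,
}

#: Species -> single-species density-clustering category.
LIVESTOCK_CATEGORIES = {
    "dairy_cow": "cattle",
    "other_cattle": "cattle",
    "sheep": "sheep",
    "horse": "horses",
    "pig": "pigs_poultry",
    "poultry": "pigs_poultry",
}

RUMINANT_OR_HORSE = ("dairy_cow", "other_cattle", "sheep", "horse")

#: Default crop vocabulary for seven-year sequences. Ley is perennial
#: grass/legume forage grown on cropland.
DEFAULT_CROPS = (
    "ley",
    "winter_wheat",
    "spring_barley",
    "oats",
    "oilseed_rape",
    "potato",
    "fallow",
)

#: Pairwise succession quality S(prev, next) in [0, 1]. Unlisted pairs fall
#: back to _S_DEFAULT. Consecutive ley is a continuing perennial stand (1.0);
#: cereal monoculture and tight oilseed/potato successions score poorly.
_S_DEFAULT = 0.7
DEFAULT_SUCCESSION: dict[tuple[str, str], float] = {
    ("ley", "ley"): 1.0,
    ("ley", "winter_wheat"): 0.95,
    ("ley", "spring_barley"): 0.9,
    ("ley", "oats"): 0.9,
    ("winter_wheat", "winter_wheat"): 0.2,
    ("spring_barley", "spring_barley"): 0.25,
    ("oats", "oats"): 0.3,
    ("oilseed_rape", "oilseed_rape"): 0.05,
    ("potato", "potato"): 0.1,
    ("winter_wheat", "spring_barley"): 0.5,
    ("spring_barley", "winter_wheat"): 0.5,
    ("oilseed_rape", "winter_wheat"): 0.95,
    ("fallow", "fallow"): 0.6,
}

#: Minimum recommended return times (years) per crop; 0 = no constraint.
DEFAULT_RETURN_TIMES = {
    "ley": 0,
    "winter_wheat": 2,
    "spring_barley": 2,
    "oats": 3,
    "oilseed_rape": 4,
    "potato": 4,
    "fallow": 0,
}


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class CropConfig:
    """Crop-sequence scoring tables and weights.

    The final parcel score is
    ``w_pair * mean pairwise succession + w_return * return-time compliance
    + w_div * (distinct crops - 1) / (years - 1)``.
    """

    crops: tuple[str, ...] = DEFAULT_CROPS
    succession: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SUCCESSION)
    )
    succession_default: float = _S_DEFAULT
    return_times: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RETURN_TIMES)
    )
    w_pair: float = 0.5
    w_return: float = 0.3
    w_div: float = 0.2
    perennial: tuple[str, ...] = ("ley",)
    years: int = 7

    def __post_init__(self) -> None:
        w = self.w_pair + self.w_return + self.w_div
        if abs(w - 1.0) > 1e-9 or min(self.w_pair, self.w_return, self.w_div) < 0:
            raise ConfigError("crop-score weights must be >= 0 and sum to 1")
        for v in self.succession.values():
            if not 0.0 <= v <= 1.0:
                raise ConfigError("succession scores must lie in [0, 1]")
        for v in self.return_times.values():
            if v < 0:
                raise ConfigError("return times must be >= 0")

    def s(self, prev: str, nxt: str) -> float:
        self._check(prev), self._check(nxt)
        return self.succession.get((prev, nxt), self.succession_default)

    def r(self, crop: str) -> int:
        self._check(crop)
        return self.return_times.get(crop, 0)

    def _check(self, crop: str) -> None:
        if crop not in self.crops:
            raise ConfigError(f"crop code {crop!r} outside vocabulary {self.crops}")


@dataclass
class AnalysisConfig:
    """All tunable constants of the assessment, with study defaults."""

    study_buffer_m: float = 50.0
    road_distance_m: float = 100.0
    population_buffer_m: float = 10_000.0
    reference_radius_m: float = 20_000.0
    alpha: float = 0.01
    strong_correlation: float = 0.5
    moderate_correlation: float = 0.3
    min_cluster_n: int = 20
    density_target_clusters: int = 4
    density_k_max: int = 12
    size_clusters: int = 5
    grid_cell_m: float = 15_000.0
    hi_percentile: float = 0.80
    lo_percentile: float = 0.20
    sequence_years: int = 7
    coverage_threshold: float = 0.5
    crpdst_spacing_m: float = 25.0
    rodvar_adjacency_m: float = 5.0
    small_scale_hours: float = 400.0
    specialist_share: float = 2.0 / 3.0
    arc_tolerance_m: float | None = None  # None -> 10-degree arc segments
    multiple_testing: str = "none"  # or "benjamini-hochberg"
    indicator_priority: tuple[str, ...] = (
        "LanVar",
        "Gra",
        "SSHab",
        "CrpSeq",
        "Acc",
        "Visit",
        "NatRes",
        "CrpDst",
        "RodVar",
    )
    lsu_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LSU_TABLE))
    crop_config: CropConfig = field(default_factory=CropConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "study_buffer_m",
            "road_distance_m",
            "population_buffer_m",
            "reference_radius_m",
            "grid_cell_m",
            "crpdst_spacing_m",
            "small_scale_hours",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.rodvar_adjacency_m < 0:
            raise ConfigError("rodvar_adjacency_m must be >= 0")
        if not 0 < self.coverage_threshold <= 1:
            raise ConfigError("coverage_threshold must lie in (0, 1]")
        if not 0 < self.lo_percentile < self.hi_percentile < 1:
            raise ConfigError("need 0 < lo_percentile < hi_percentile < 1")
        if self.multiple_testing not in ("none", "benjamini-hochberg"):
            raise ConfigError("multiple_testing must be 'none' or 'benjamini-hochberg'")
        for sp, c in self.lsu_table.items():
            if c <= 0:
                raise ConfigError(f"LSU coefficient for {sp} must be > 0")
        if set(self.indicator_priority) != set(INDICATORS):
            raise ConfigError("indicator_priority must cover all nine indicators")

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        cc = d["crop_config"]
        cc["succession"] = {f"{a}|{b}": v for (a, b), v in cc["succession"].items()}
        cc["crops"] = list(cc["crops"])
        cc["perennial"] = list(cc["perennial"])
        d["indicator_priority"] = list(d["indicator_priority"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if "crop_config" in d and isinstance(d["crop_config"], dict):
            cc = dict(d["crop_config"])
            if "succession" in cc:
                cc["succession"] = {
                    tuple(k.split("|")): v for k, v in cc["succession"].items()
                }
            for key in ("crops", "perennial"):
                if key in cc:
                    cc[key] = tuple(cc[key])
            d["crop_config"] = CropConfig(**cc)
        if "indicator_priority" in d:
            d["indicator_priority"] = tuple(d["indicator_priority"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def deviations_from_defaults(cfg: AnalysisConfig) -> dict[str, tuple[Any, Any]]:
    """Map of field -> (value, default) for every constant off its default."""
    ref = AnalysisConfig()
    out: dict[str, tuple[Any, Any]] = {}
    for f in dataclasses.fields(AnalysisConfig):
        if f.name == "seed":
            continue
        a, b = getattr(cfg, f.name), getattr(ref, f.name)
        if a != b:
            out[f.name] = (a, b)
    return out
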