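"""Configuration objects and their YAML (de)serialization.

The on-disk config format is a plain YAML mapping carrying a ``schema: 1``
key; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

SCHEMA_VERSION = 1

MODES = ("walk", "transit", "bike")

CATEGORIES = ("demographics", "environment", "urban_morphology")


@dataclass
class CovariateSpec:
    """One synthetic zonal covariate.

    ``spatial_range`` (meters) controls the Gaussian-kernel smoothing of the
    underlying white-noise field: 0 means spatially independent values.
    ``correlate_with`` optionally names an earlier covariate whose latent
    field this one shares with Pearson correlation ``correlation``.
    """

    name: str
    category: str = "demographics"
    kind: str = "extensive"
    mean: float = 100.0
    sd: float = 25.0
    spatial_range: float = 1000.0
    clip_nonneg: bool = True
    correlate_with: str | None = None
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"covariate {self.name}: bad category {self.category!r}")
        if self.kind not in ("extensive", "intensive"):
            raise ValueError(f"covariate {self.name}: bad kind {self.kind!r}")
        if self.sd < 0 or self.spatial_range < 0:
            raise ValueError(f"covariate {self.name}: sd and spatial_range must be >= 0")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError(f"covariate {self.name}: |correlation| must be < 1")


def default_covariates() -> list[CovariateSpec]:
    """Covariates in the three categories a food-access study controls for:
    demographics, environment, and urban morphology (space-syntax style
    metrics are generated as intensive zone attributes, not computed from
    geometry)."""
    return [
        CovariateSpec("population", "demographics", "extensive", 1200, 400, 1500),
        CovariateSpec("male", "demographics", "extensive", 580, 200, 1500,
                      correlate_with="population", correlation=0.85),
        CovariateSpec("low_wage_workers", "demographics", "extensive", 300, 120, 2000),
        CovariateSpec("race_white", "demographics", "extensive", 700, 300, 2500),
        CovariateSpec("high_school_diploma", "demographics", "extensive", 500, 180, 2000),
        CovariateSpec("crime", "environment", "extensive", 40, 20, 1200),
        CovariateSpec("pedestrian_intersections", "environment", "extensive", 25, 8, 800),
        CovariateSpec("multimodal_intersections", "environment", "extensive", 12, 5, 800),
        CovariateSpec("roads_length", "environment", "extensive", 9000, 2000, 800),
        CovariateSpec("park_area", "environment", "extensive", 30000, 15000, 1500),
        CovariateSpec("shortest_line_distance", "urban_morphology", "intensive", 450, 90, 1200),
        CovariateSpec("shortest_path_angularity", "urban_morphology", "intensive", 2.1, 0.5, 1200),
        CovariateSpec("isovist_area", "urban_morphology", "intensive", 5200, 1400, 1000),
        CovariateSpec("visual_depth", "urban_morphology", "intensive", 6.5, 1.5, 1000),
        CovariateSpec("occlusivity", "urban_morphology", "intensive", 310, 80, 1000),
    ]


@dataclass
class PlantedEffects:
    """Optional spatially autocorrelated outcome planted on outlet locations
    (used for estimator-recovery experiments, not by the geometric pipeline)."""

    beta: list[float] = field(default_factory=lambda: [1.0, -0.5])
    rho: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("planted effects: sigma must be > 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("planted effects: |rho| must be < 1")


@dataclass
class SyntheticCityConfig:
    """Parameters of the synthetic city generator.

    Defaults emulate a mid-sized, Flint-like city: an 8 x 8 km extent with a
    400 m perturbed street grid, 57 restaurants + 9 grocers, ~100 covariate
    zones, and 4 transit routes with ~800 m stop spacing.
    """

    seed: int = 0
    extent: tuple[float, float] = (8000.0, 8000.0)
    grid_spacing: float = 400.0
    edge_jitter: float = 0.15
    n_restaurants: int = 57
    n_grocers: int = 9
    revenue_lognormal: tuple[float, float] = (13.1, 0.8)   # median ~ $490k / year
    sqft_lognormal: tuple[float, float] = (7.8, 0.5)       # median ~ 2400 sq ft
    n_zones: int = 100
    covariates: list[CovariateSpec] = field(default_factory=default_covariates)
    n_transit_routes: int = 4
    stop_spacing: float = 800.0
    planted: PlantedEffects = field(default_factory=PlantedEffects)

    def __post_init__(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if not 0 <= self.edge_jitter < 0.5:
            raise ValueError("edge_jitter must lie in [0, 0.5)")
        if self.n_restaurants < 0 or self.n_grocers < 0:
            raise ValueError("outlet counts must be >= 0")
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")
        if self.n_transit_routes < 0 or self.stop_spacing <= 0:
            raise ValueError("invalid transit parameters")
        names = [c.name for c in self.covariates]
        if len(names) != len(set(names)):
            raise ValueError("duplicate covariate names")


@dataclass
class RAIConfig:
    """Revealed Accessibility Index settings.

    decay_exponent is the gravity distance-decay power (-2: inverse-square);
    min_distance_km floors pairwise distances so co-located outlets cannot
    produce an unbounded index; competitor_scope selects which outlets count
    as competitors of outlet j.
    """

    decay_exponent: float = -2.0
    min_distance_km: float = 0.05
    competitor_scope: str = "same_service_area"  # or "all_city"
    weight_normalization: str = "max"            # or "none"

    def __post_init__(self) -> None:
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be negative")
        if self.min_distance_km <= 0:
            raise ValueError("min_distance_km must be positive")
        if self.competitor_scope not in ("same_service_area", "all_city"):
            raise ValueError(f"unknown competitor_scope {self.competitor_scope!r}")
        if self.weight_normalization not in ("max", "none"):
            raise ValueError(f"unknown weight_normalization {self.weight_normalization!r}")


@dataclass
class PipelineConfig:
    """One reproducible end-to-end run."""

    city: SyntheticCityConfig = field(default_factory=SyntheticCityConfig)
    modes: tuple[str, ...] = MODES
    rai: RAIConfig = field(default_factory=RAIConfig)
    screening_alpha: float = 0.05
    vif_threshold: float = 10.0
    models: tuple[str, ...] = ("ols", "sar", "gwr")
    harmonize_screening: bool = True
    output_dir: str = "run_output"
    seed: int | None = None  # overrides city.seed when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes {unknown}")
        unknown = set(self.models) - {"ols", "sar", "gwr"}
        if unknown:
            raise ValueError(f"unknown models {unknown}")
        if not 0 < self.screening_alpha < 1:
            raise ValueError("screening_alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# YAML round-trip


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(cfg: SyntheticCityConfig | PipelineConfig, path: str | Path) -> None:
    doc = {"schema": SCHEMA_VERSION,
           "kind": type(cfg).__name__,
           "config": _to_plain(cfg)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _build_city(d: dict) -> SyntheticCityConfig:
    d = dict(d)
    d["extent"] = tuple(d.get("extent", (8000.0, 8000.0)))
    d["revenue_lognormal"] = tuple(d.get("revenue_lognormal", (13.1, 0.8)))
    d["sqft_lognormal"] = tuple(d.get("sqft_lognormal", (7.8, 0.5)))
    if "covariates" in d:
        d["covariates"] = [CovariateSpec(**c) for c in d["covariates"]]
    if "planted" in d:
        d["planted"] = PlantedEffects(**d["planted"])
    return SyntheticCityConfig(**d)


def load_config(path: str | Path) -> SyntheticCityConfig | PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"{path}: expected a mapping with schema: {SCHEMA_VERSION}")
    kind, d = doc.get("kind"), doc.get("config", {})
    if kind == "SyntheticCityConfig":
        return _build_city(d)
    if kind == "PipelineConfig":
        d = dict(d)
        if "city" in d:
            d["city"] = _build_city(d["city"])
        if "rai" in d:
            d["rai"] = RAIConfig(**d["rai"])
        for key in ("modes", "models"):
            if key in d:
                d[key] = tuple(d[key])
        return PipelineConfig(**d)
    raise ValueError(f"{path}: unknown config kind {kind!r}")
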