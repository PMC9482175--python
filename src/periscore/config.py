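"""Configuration objects for every pipeline stage, with YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _default_base_densities() -> dict:
    # Stromal cell intensities (1/mm^2), order-of-magnitude choices in the
    # tens-to-thousands range typical of colorectal TMA cores.
    return {
        "CD8": 300.0,
        "GZMB": 150.0,
        "CD68": 400.0,
        "CD163": 350.0,
        "double_negative": 1000.0,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic TMA cohort generator.

    ``core_diameter`` is in micrometres (600 emulates the 0.6 mm cores of
    a primary cohort, 1000 the 1.0 mm validation-style cores).
    ``proximity_enrichment`` multiplies a marker's stromal intensity within
    25 um of the tumour mask.  Survival times are exponential with hazard
    ``baseline_hazard * hazard_ratio_high_vs_low**1{high}`` where the
    latent high/low group also controls whether enrichment is applied.
    """

    seed: int = 0
    n_patients: int = 20
    cores_per_patient: int = 2
    core_diameter: float = 600.0  # um
    pixel_size: float = 0.25  # um / pixel
    regions: tuple = ("CT", "FR", "ME", "NE")
    base_densities: dict = field(default_factory=_default_base_densities)
    tumour_cell_density: float = 1500.0  # 1/mm^2 inside tumour mask
    tumour_fraction: float = 0.3
    proximity_enrichment: dict = field(default_factory=dict)
    enrichment_radius: float = 25.0  # um
    hazard_ratio_high_vs_low: float = 0.25
    baseline_hazard: float = 0.02  # 1/month
    censor_rate: float = 0.2
    follow_up_horizon: float = 120.0  # months
    panel: int = 1
    confound_covariates: bool = False

    def validate(self) -> None:
        if self.core_diameter <= 0:
            raise ConfigurationError("core_diameter must be positive")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if not (0.0 <= self.tumour_fraction < 1.0):
            raise ConfigurationError("tumour_fraction must lie in [0, 1)")
        if self.hazard_ratio_high_vs_low <= 0:
            raise ConfigurationError("hazard ratio must be positive")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ConfigurationError("censor_rate must lie in [0, 1]")
        if any(v < 0 for v in self.base_densities.values()):
            raise ConfigurationError("densities must be non-negative")
        if self.n_patients < 0 or self.cores_per_patient < 0:
            raise ConfigurationError("counts must be non-negative")
        unknown = set(self.regions) - {"CT", "FR", "ME", "NE"}
        if unknown:
            raise ConfigurationError(f"unknown regions: {sorted(unknown)}")


@dataclass
class UnmixConfig:
    """Settings of the non-negative group-sparse stain unmixing.

    ``lam`` is the sparsity weight on the per-stain concentration (with one
    stain per group the group penalty is the non-negative L1 norm).
    Pixels whose total optical density falls below ``od_floor`` are treated
    as background and skipped.
    """

    lam: float = 0.1
    background_intensity: float = 255.0
    od_floor: float = 0.02
    tol: float = 1e-8
    max_iter: int = 1000

    def validate(self) -> None:
        if self.lam < 0:
            raise ConfigurationError("lambda must be non-negative")
        if self.background_intensity <= 0:
            raise ConfigurationError("background intensity must be positive")


@dataclass
class ThresholdSet:
    """Channel-intensity thresholds for tissue/tumour/cell detection.

    Mirrors the manually tuned per-cohort threshold sets of a brightfield
    multiplex workflow; separate instances are used per cohort because
    overall stain intensities differ between staining runs.
    """

    tissue_od_min: float = 0.05
    panck_min: float = 0.25
    nucleus_od_min: float = 0.5
    cd8_min: float = 0.15
    cd68_min: float = 0.15
    gzmb_min: float = 0.15
    cd163_min: float = 0.15
    min_nucleus_area: float = 6.0  # um^2
    max_nucleus_area: float = 250.0  # um^2
    smooth_sigma_um: float = 1.0
    min_peak_separation_um: float = 4.0
    saturation_od: float = 2.0
    min_solidity: float = 0.5
    measure_radius_um: float = 3.0

    def validate(self) -> None:
        vals = (
            self.tissue_od_min, self.panck_min, self.nucleus_od_min,
            self.cd8_min, self.cd68_min, self.gzmb_min, self.cd163_min,
        )
        if any(v < 0 for v in vals):
            raise ConfigurationError("thresholds must be non-negative")
        if not self.min_nucleus_area < self.max_nucleus_area:
            raise ConfigurationError("min_nucleus_area must be < max_nucleus_area")

    def marker_threshold(self, marker: str) -> float:
        return {
            "CD8": self.cd8_min,
            "CD68": self.cd68_min,
            "GZMB": self.gzmb_min,
            "CD163": self.cd163_min,
        }[marker]


@dataclass
class ZoneSpec:
    """Tumour-proximity zone radii (um); ``total`` (no limit) is implied."""

    radii: tuple = (10.0, 25.0, 50.0, 100.0)

    def validate(self) -> None:
        r = tuple(self.radii)
        if any(x <= 0 for x in r) or any(b <= a for a, b in zip(r, r[1:])):
            raise ConfigurationError("radii must be positive and strictly increasing")

    @property
    def labels(self) -> tuple:
        return tuple(self.radii) + ("total",)


@dataclass
class PipelineConfig:
    """Top-level configuration: one block per stage plus analysis options."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    unmixing: UnmixConfig = field(default_factory=UnmixConfig)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    zones: ZoneSpec = field(default_factory=ZoneSpec)
    analysis_region: str = "CT"
    analysis_radius: object = 25.0
    endpoint: str = "overall"
    covariates: tuple = ("tnm_stage", "postop_chemo")
    ties_method: str = "efron"

    def validate(self) -> None:
        self.simulation.validate()
        self.unmixing.validate()
        self.thresholds.validate()
        self.zones.validate()


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _from_plain(f.type, v)
        kwargs[f.name] = v
    return cls(**kwargs)


_NESTED = {
    "simulation": SimulationConfig,
    "unmixing": UnmixConfig,
    "thresholds": ThresholdSet,
    "zones": ZoneSpec,
}


def config_to_yaml(config: PipelineConfig) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=False)


def config_from_yaml(text: str) -> PipelineConfig:
    data = yaml.safe_load(text) or {}
    kwargs = {}
    for f in dataclasses.fields(PipelineConfig):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in _NESTED:
            sub = {}
            for sf in dataclasses.fields(_NESTED[f.name]):
                if sf.name in v:
                    sv = v[sf.name]
                    sub[sf.name] = tuple(sv) if isinstance(sv, list) else sv
            v = _NESTED[f.name](**sub)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    cfg = PipelineConfig(**kwargs)
    # tuples inside nested configs arrive as lists from YAML
    if isinstance(cfg.simulation.regions, list):
        cfg.simulation.regions = tuple(cfg.simulation.regions)
    if isinstance(cfg.zones.radii, list):
        cfg.zones.radii = tuple(cfg.zones.radii)
    cfg.validate()
    return cfg
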