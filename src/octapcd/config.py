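"""Pipeline configuration: a single human-readable YAML file.

The configuration round-trips losslessly through its serialized form; every
threshold, convention and seed used anywhere in the pipeline lives here, so
a config plus the package version pins a bit-identical run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .errors import ValidationError


@dataclass
class GeometryConfig:
    inner_diameter_mm: float = 1.95
    outer_diameter_mm: float = 3.45
    nasal_right_for_od: bool = True


@dataclass
class SegmentationConfig:
    method: str = "local_mean"
    window_um: float = 150.0
    offset: float = 0.15
    caliber_cutoff_um: float = 32.0
    rim_dilation_px: int = 1


@dataclass
class DensityConfig:
    convention: str = "include_large"


@dataclass
class QualityConfig:
    enforce_ssi_gate: bool = True
    min_ssi: float = 48.0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    bonferroni: bool = True
    roc_metric: str = "pcd_nasal"
    roc_positive_group: str = "papilledema"
    roc_negative_group: str = "pseudopapilledema"


@dataclass
class GroupSimConfig:
    """Image-level simulation parameters for one diagnostic group."""

    name: str
    n_subjects: int
    n_eyes: int
    capillary_fraction_mean: float
    capillary_fraction_sd: float = 0.04
    capillary_fraction_subject_sd: float = 0.025
    ssi_mean: float = 65.0
    ssi_sd: float = 5.0


@dataclass
class SimulateConfig:
    image_px: int = 304
    field_mm: float = 4.5
    n_large_vessels: int = 8
    noise_sd: float = 0.05
    groups: List[GroupSimConfig] = field(
        default_factory=lambda: [
            GroupSimConfig("papilledema", 4, 7, 0.32),
            GroupSimConfig("pseudopapilledema", 4, 7, 0.27),
            GroupSimConfig("control", 6, 6, 0.34),
        ]
    )


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    density: DensityConfig = field(default_factory=DensityConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> Dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", {})
        groups = [GroupSimConfig(**g) for g in sim.pop("groups", [])]
        simulate = SimulateConfig(**sim)
        if groups:
            simulate.groups = groups
        return cls(
            seed=d.pop("seed", 0),
            simulate=simulate,
            geometry=GeometryConfig(**d.pop("geometry", {})),
            segmentation=SegmentationConfig(**d.pop("segmentation", {})),
            density=DensityConfig(**d.pop("density", {})),
            quality=QualityConfig(**d.pop("quality", {})),
            stats=StatsConfig(**d.pop("stats", {})),
        )

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        """Load from a YAML file path or a YAML string."""
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            path = Path(source)
            if not path.exists():
                raise ValidationError(f"config file not found: {path}")
            text = path.read_text()
        else:
            text = str(source)
        return cls.from_dict(yaml.safe_load(text) or {})
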