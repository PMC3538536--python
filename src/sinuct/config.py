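"""Run configuration: one YAML file drives the whole pipeline.

The global ``seed`` is the single source of randomness; per-stage seeds are
derived from it deterministically, so a config + seed pair reproduces a run
bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .optics import AcquisitionGeometry

__all__ = [
    "PhantomConfig",
    "PreprocessConfig",
    "ReconConfig",
    "SegmentConfig",
    "RunConfig",
]


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 9.0
    grade: str = "mild"
    n_sinusoids: int = 5
    diameter_range_um: tuple[float, float] = (80.0, 200.0)
    #: label id -> thrombus volume fraction (applied after generation)
    thrombus: dict[int, float] = field(default_factory=dict)


@dataclass
class PreprocessConfig:
    smooth_strength: float = 1.5
    ring_correct: bool = True
    ring_window: int = 15
    #: unsharp-mask enhancement of reconstructed slices; 0 disables.
    #: Enhancement sharpens the display volume but biases morphometry, so
    #: the measurement path keeps it off by default.
    edge_enhance_amount: float = 0.0
    edge_enhance_radius: float = 2.0


@dataclass
class ReconConfig:
    filter_name: str = "ram-lak"


@dataclass
class SegmentConfig:
    min_voxels: int = 27
    median_size: int = 3
    tissue_erosion: int = 3
    thrombus_brightness_sigma: float = 4.0
    thrombus_min_voxels: int = 27
    #: restrict segmentation to the cylindrical sample-holder interior
    #: (the ROI an operator would draw); margin is in voxels from the
    #: volume edge and should exceed the phantom's wall margin so the
    #: strong wall fringes stay outside the ROI.
    use_cylinder_roi: bool = True
    roi_margin: int = 4


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    output_dir: str = "runs/run"
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed drives every stochastic stage
        self.geometry.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        sections = {
            "phantom": PhantomConfig,
            "geometry": AcquisitionGeometry,
            "preprocess": PreprocessConfig,
            "recon": ReconConfig,
            "segment": SegmentConfig,
        }
        kwargs = {}
        for name, cls_ in sections.items():
            if name in payload:
                section = dict(payload.pop(name))
                if name == "phantom":
                    section["grid_shape"] = tuple(section.get("grid_shape", (64, 64, 64)))
                    section["diameter_range_um"] = tuple(
                        section.get("diameter_range_um", (80.0, 200.0))
                    )
                    section["thrombus"] = {
                        int(k): float(v) for k, v in (section.get("thrombus") or {}).items()
                    }
                kwargs[name] = cls_(**section)
        kwargs.update(payload)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
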