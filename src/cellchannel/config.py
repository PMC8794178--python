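"""Pipeline configuration: YAML schema, defaults and validation.

Defaults equal the protocol's stated values everywhere one exists
(segmentation area band 2000/8000 px, crop 150 px, flat-field sigma 200 px,
gating radius 30 px and posterior threshold 0.8, mask radius 50 px, the CNN
training hyperparameters); every other knob is a documented design default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cellchannel.classifiers import TrainSpec
from cellchannel.synthetic import SyntheticConfig


@dataclass(frozen=True)
class SegmentationParams:
    polarity: str = "dark"
    closing_radius: int = 3
    smoothing_sigma: float = 4.0
    min_peak_distance: int = 10
    min_area_px: int = 2000
    max_area_px: int = 8000


@dataclass(frozen=True)
class LabellingParams:
    radius_px: int = 30
    posterior_threshold: float = 0.8
    flatten_sigma: float = 200.0
    gmm_seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    labelling: LabellingParams = field(default_factory=LabellingParams)
    training: TrainSpec = field(default_factory=TrainSpec)
    crop_channels: tuple[str, ...] = ("ph", "dic", "bf")
    trim_seed: int = 0
    #: grid plan entries, see evaluation.run_grid
    plan: tuple = (
        {"name": "size_svm", "kind": "svm_size"},
        {"name": "dic", "kind": "cnn", "channels": ["dic"]},
    )
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["plan"] = [dict(p) for p in self.plan]
        return d


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys under {path}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list) and f.name not in ("plan",):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    sections = {
        "synthetic": SyntheticConfig,
        "segmentation": SegmentationParams,
        "labelling": LabellingParams,
        "training": TrainSpec,
    }
    known = set(sections) | {"crop_channels", "trim_seed", "plan", "out_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for key, cls in sections.items():
        if key in raw:
            kwargs[key] = _build(cls, raw[key] or {}, key)
    if "crop_channels" in raw:
        kwargs["crop_channels"] = tuple(raw["crop_channels"])
    for key in ("trim_seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    if "plan" in raw:
        kwargs["plan"] = tuple(dict(p) for p in raw["plan"])
    cfg = PipelineConfig(**kwargs)
    cfg.synthetic.validate()
    return cfg
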