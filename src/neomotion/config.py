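"""Structured run configuration: one YAML file drives every command.

Precedence is CLI override > config file > dataclass defaults.  Unknown
keys anywhere in the file are rejected - silent typos in a config are how
irreproducible runs happen.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .classifier import ForestConfig
from .denoise import DenoiseConfig
from .features import FeatureConfig
from .synthetic import (
    EventConfig,
    NoiseConfig,
    RespirationConfig,
    SceneConfig,
    StudyConfig,
)

logger = logging.getLogger(__name__)

# tuple-typed dataclass fields arrive from YAML as lists
_TUPLE_FIELDS = {
    "pct_range_mm", "median_kernels", "area_thresholds_mm", "sum_thresholds_mm",
    "frame_shape", "body_axes_px", "chest_axes_px", "duration_s_range",
    "region_px_range", "amplitude_mm_range", "valid_range_mm",
    "distance_range_mm", "clips_per_subject",
}


@dataclass
class Paths:
    dataset_dir: str = "dataset"
    model_path: str = "model.joblib"
    report_dir: str = "report"


@dataclass
class RunConfig:
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    paths: Paths = field(default_factory=Paths)
    seed: int = 0
    log_level: str = "INFO"


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise TypeError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = sorted(set(data) - set(known))
    if unknown:
        raise ValueError(f"{context}: unknown keys {unknown}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = _nested_dataclass(f)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{context}.{name}")
        elif name in _TUPLE_FIELDS and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _nested_dataclass(f: dataclasses.Field):
    # resolve the dataclass type of nested config fields by name
    mapping = {
        "denoise": DenoiseConfig,
        "features": FeatureConfig,
        "forest": ForestConfig,
        "study": StudyConfig,
        "scene": SceneConfig,
        "respiration": RespirationConfig,
        "events": EventConfig,
        "noise": NoiseConfig,
        "paths": Paths,
    }
    return mapping.get(f.name)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML, applying keyword overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    cfg = _build(RunConfig, data, "run config")
    if overrides:
        cfg = dataclasses.replace(
            cfg, **{k: v for k, v in overrides.items() if v is not None}
        )
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    """Serialize a RunConfig back to YAML (round-trips with load_config)."""
    path = Path(path)

    def enc(obj):
        if is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(enc(cfg), fh, sort_keys=False)
    return path


__all__ = ["RunConfig", "Paths", "load_config", "dump_config"]
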