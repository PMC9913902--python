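"""Structured pipeline configuration loaded from YAML.

Every section is validated against the owning module's invariants at load
time and unknown keys are rejected. A single global seed fans out to
per-stage seeds via stable hashing of the stage name.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .phantom import PhantomSpec, spec_from_dict


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the global one."""
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0])


def _from_dict(cls, d: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class PreprocessConfig:
    threshold: float = 0.05
    downsample: bool = True

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValidationError("preprocess.threshold must be in (0, 1)")


@dataclass(frozen=True)
class SegmentConfig:
    regions: int = 5
    q: float = 0.8

    def __post_init__(self):
        if self.regions < 2:
            raise ValidationError("segment.regions must be >= 2")
        if self.q <= 0 or self.q == 1:
            raise ValidationError("segment.q must be > 0 and != 1")


@dataclass(frozen=True)
class SSOSection:
    population_size: int = 25
    max_iterations: int = 100
    attenuation_rate: float = 1.0
    mask_change_prob: float = 0.7
    mask_one_prob: float = 0.1

    def __post_init__(self):
        if self.population_size < 2 or self.max_iterations < 1:
            raise ValidationError("sso population/iterations out of range")
        if self.attenuation_rate <= 0:
            raise ValidationError("sso.attenuation_rate must be > 0")
        for p in (self.mask_change_prob, self.mask_one_prob):
            if not 0 <= p <= 1:
                raise ValidationError("sso probabilities must be in [0, 1]")


@dataclass(frozen=True)
class FeaturesConfig:
    energy_fraction: float = 0.99

    def __post_init__(self):
        if not 0 < self.energy_fraction <= 1:
            raise ValidationError("features.energy_fraction must be in (0, 1]")


@dataclass(frozen=True)
class EnsembleConfig:
    standardize: bool = False


@dataclass(frozen=True)
class EvaluateConfig:
    mode: str = "holdout"
    reps: int = 20
    k: int = 10
    train_frac: float = 0.7

    def __post_init__(self):
        if self.mode not in ("holdout", "cv"):
            raise ValidationError("evaluate.mode must be 'holdout' or 'cv'")
        if self.reps < 1 or self.k < 2:
            raise ValidationError("evaluate.reps/k out of range")
        if not 0 < self.train_frac < 1:
            raise ValidationError("evaluate.train_frac must be in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    sso: SSOSection = field(default_factory=SSOSection)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        sections = {
            "phantom": lambda v: spec_from_dict(v),
            "preprocess": lambda v: _from_dict(PreprocessConfig, v, "preprocess"),
            "segment": lambda v: _from_dict(SegmentConfig, v, "segment"),
            "sso": lambda v: _from_dict(SSOSection, v, "sso"),
            "features": lambda v: _from_dict(FeaturesConfig, v, "features"),
            "ensemble": lambda v: _from_dict(EnsembleConfig, v, "ensemble"),
            "evaluate": lambda v: _from_dict(EvaluateConfig, v, "evaluate"),
        }
        kwargs = {}
        for key, value in d.items():
            if key in sections:
                kwargs[key] = sections[key](value or {})
            elif key == "seed":
                kwargs["seed"] = int(value)
            elif key == "log_level":
                kwargs["log_level"] = str(value)
            else:
                raise ValidationError(f"unknown top-level config key: {key!r}")
        cfg = cls(**kwargs)
        if "phantom" not in kwargs:
            # Phantom seed follows the global seed unless set explicitly.
            cfg = dataclasses.replace(
                cfg, phantom=dataclasses.replace(cfg.phantom,
                                                 seed=stage_seed(cfg.seed, "phantom")))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        return cls.from_dict(data or {})
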