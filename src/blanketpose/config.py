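"""Pipeline configuration: one YAML/JSON schema for the whole run, with
a single global seed from which every module's seed is derived.

Seed fan-out is a documented hash: ``derive_seed(global_seed, name)``
takes the first 4 bytes of SHA-256 of ``"{global_seed}:{name}"`` modulo
2**31, so no two stages ever share a generator state by accident and a
rerun with the same global seed reproduces every stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .augmentation import AffineConfig
from .errors import ConfigurationError
from .model import ModelConfig, TrainConfig

__all__ = ["SimulateConfig", "AugmentConfig", "SplitConfig", "PipelineConfig", "derive_seed"]


def derive_seed(global_seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SimulateConfig:
    n_train: int = 20
    n_test: int = 8
    frame_rows: int = 128
    frame_cols: int = 96
    noise_sd: float = 5.0
    #: blanket conditions available for *training* participants; test
    #: participants are always rendered under all four conditions.
    train_blankets: tuple[str, ...] = ("thick", "medium", "thin", "none")

    def __post_init__(self):
        if self.n_train < 1 or self.n_test < 0:
            raise ConfigurationError("need at least one training participant")


@dataclass(frozen=True)
class AugmentConfig:
    affine: AffineConfig = field(default_factory=AffineConfig)
    fusion: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if self.model.input_shape != (self.simulate.frame_rows, self.simulate.frame_cols):
            raise ConfigurationError(
                "model input_shape must match the simulated frame size"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimulateConfig(**{**d.get("simulate", {}),
                                "train_blankets": tuple(d.get("simulate", {}).get(
                                    "train_blankets", SimulateConfig().train_blankets))})
        aug_d = dict(d.get("augment", {}))
        affine = AffineConfig(**aug_d.pop("affine", {}))
        aug = AugmentConfig(affine=affine, **aug_d)
        model_d = dict(d.get("model", {}))
        for key in ("input_shape", "heads", "channels"):
            if key in model_d:
                model_d[key] = tuple(model_d[key])
        model = ModelConfig(**model_d)
        train = TrainConfig(**d.get("train", {}))
        return cls(seed=int(d.get("seed", 0)), simulate=sim, augment=aug,
                   model=model, train=train)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
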