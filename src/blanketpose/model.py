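"""Dual-head posture classifier: shared CNN backbone, dropout, and two
parallel softmax heads trained jointly.

The coarse head predicts the 4 standard postures, the fine head the 7
detailed postures; the training loss is the plain sum of the two
categorical cross-entropies,

    L = CE_coarse(y, p) + CE_fine(y, p),  CE(y, p) = -sum_i y_i log p_i.

Training is two-phase: first on the synthesized blanket-fusion dataset
(regenerated with fresh mixing weights every epoch), then on the
original frames, both with bounded affine augmentation.  Optimization
is Adam at a fixed learning rate of 1e-4 with decoupled L2 weight decay
5e-4; dropout before the heads defaults to drop probability 0.8.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from ._nn import Adam, DualHeadNet, cross_entropy, one_hot
from .dataset import CoarsePosture, FinePosture, coarse_codes_from_fine
from .errors import ConfigurationError

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "PostureClassifier",
    "build_model",
    "joint_loss",
    "train_two_phase",
    "predict",
    "Prediction",
]


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_cnn"
    dropout_rate: float = 0.8
    input_shape: tuple[int, int] = (128, 96)
    heads: tuple[int, int] = (4, 7)
    channels: tuple[int, int, int] = (16, 32, 64)
    dense_units: int = 128

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.backbone != "small_cnn":
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    l2_weight: float = 5e-4
    epochs_phase1: int = 40
    epochs_phase2: int = 10
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.epochs_phase1 < 0 or self.epochs_phase2 < 0:
            raise ConfigurationError("epoch counts must be non-negative")


class PostureClassifier:
    """The dual-head network plus its configuration."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.net = DualHeadNet(
            input_shape=config.input_shape,
            channels=config.channels,
            dense_units=config.dense_units,
            heads=config.heads,
            dropout_rate=config.dropout_rate,
            seed=seed,
        )

    def forward(self, frames: np.ndarray, training: bool = False, rng=None):
        pc, pf, _ = self.net.forward(frames, training=training, rng=rng)
        return pc, pf

    def predict_proba(self, frames: np.ndarray):
        """Deterministic inference-mode probabilities for a batch."""
        return self.forward(np.asarray(frames), training=False)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.params)
        sidecar = {"model_config": asdict(self.config)}
        if extra:
            sidecar.update(extra)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PostureClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = sidecar["model_config"]
        for key in ("input_shape", "heads", "channels"):
            cfg[key] = tuple(cfg[key])
        model = cls(ModelConfig(**cfg))
        with np.load(path.with_suffix(".npz")) as data:
            model.net.params = {k: data[k] for k in data.files}
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> PostureClassifier:
    """Construct an untrained dual-head classifier."""
    return PostureClassifier(config or ModelConfig(), seed=seed)


def joint_loss(
    y_coarse: np.ndarray,
    p_coarse: np.ndarray,
    y_fine: np.ndarray,
    p_fine: np.ndarray,
) -> float:
    """Sum of coarse and fine categorical cross-entropies, averaged over
    the batch.  Accepts one-hot targets and predicted distributions;
    predicted probabilities are floored at 1e-12 inside the log."""
    y_coarse, p_coarse = np.atleast_2d(y_coarse), np.atleast_2d(p_coarse)
    y_fine, p_fine = np.atleast_2d(y_fine), np.atleast_2d(p_fine)
    ce_c = cross_entropy(y_coarse, p_coarse)
    ce_f = cross_entropy(y_fine, p_fine)
    return float((ce_c + ce_f).mean())


@dataclass
class Prediction:
    coarse: CoarsePosture
    fine: FinePosture
    p_coarse: np.ndarray
    p_fine: np.ndarray


def predict(model: PostureClassifier, frame: np.ndarray) -> Prediction:
    """Classify one frame; each head's class is its argmax (ties break to
    the lowest class code)."""
    pc, pf = model.predict_proba(frame[None, :, :])
    return Prediction(
        coarse=CoarsePosture(int(np.argmax(pc[0]))),
        fine=FinePosture(int(np.argmax(pf[0]))),
        p_coarse=pc[0],
        p_fine=pf[0],
    )


def predict_batch(model: PostureClassifier, frames: np.ndarray):
    """Vectorized argmax predictions: (coarse codes, fine codes, p_c, p_f)."""
    pc, pf = model.predict_proba(frames)
    return pc.argmax(axis=1), pf.argmax(axis=1), pc, pf


EpochFn = Callable[[int, np.random.Generator], tuple[np.ndarray, np.ndarray]]


def _run_epochs(
    model: PostureClassifier,
    epoch_fn: EpochFn,
    n_epochs: int,
    optimizer: Adam,
    batch_size: int,
    rng: np.random.Generator,
) -> list[float]:
    history = []
    net = model.net
    n_coarse, n_fine = model.config.heads
    for epoch in range(n_epochs):
        frames, fine_codes = epoch_fn(epoch, rng)
        if len(frames) == 0:
            raise ConfigurationError("empty training epoch")
        coarse_codes = coarse_codes_from_fine(fine_codes)
        order = rng.permutation(len(frames))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            x = frames[idx]
            y_c = one_hot(coarse_codes[idx], n_coarse)
            y_f = one_hot(fine_codes[idx], n_fine)
            pc, pf, cache = net.forward(x, training=True, rng=rng)
            losses.append(joint_loss(y_c, pc, y_f, pf) * len(idx))
            grads = net.backward(cache, y_c, y_f)
            optimizer.step(net.params, grads)
        history.append(sum(losses) / len(order))
    return history


def train_two_phase(
    model: PostureClassifier,
    synthesized: EpochFn | None,
    original: EpochFn,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[float]]:
    """Two-phase training schedule.

    Phase 1 trains on the synthesized (blanket-fusion) stream, whose
    ``epoch_fn`` is called once per epoch so mixing weights are fresh;
    phase 2 trains on the original frames.  Either phase may have zero
    epochs (phase 1 = 0 is the no-fusion ablation).  Returns per-epoch
    mean training losses, ``{"phase1": [...], "phase2": [...]}``.
    """
    if config.epochs_phase1 > 0 and synthesized is None:
        raise ConfigurationError("phase 1 requested but no synthesized stream given")
    rng = rng or np.random.default_rng(config.seed)
    optimizer = Adam(
        model.net.params, lr=config.learning_rate, weight_decay=config.l2_weight
    )
    history = {"phase1": [], "phase2": []}
    if config.epochs_phase1 > 0:
        history["phase1"] = _run_epochs(
            model, synthesized, config.epochs_phase1, optimizer, config.batch_size, rng
        )
    if config.epochs_phase2 > 0:
        history["phase2"] = _run_epochs(
            model, original, config.epochs_phase2, optimizer, config.batch_size, rng
        )
    return history
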