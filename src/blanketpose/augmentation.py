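"""Training-time data augmentation: bounded affine transforms and
intraclass blanket fusion (mix-up across blanket conditions).

Blanket fusion forms the convex combination ``u*img1 + (1-u)*img2`` of
two depth frames of the *same participant in the same posture* under
two *different* blanket conditions, with ``u ~ U(0,1)`` drawn fresh for
every pair in every epoch.  Because the pose is held fixed across
conditions, the result is a plausible depth image of a hypothetical
intermediate blanket, and the posture label carries over unchanged.
Four blanket conditions give C(4,2) = 6 such hypothetical conditions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import ndimage

from .dataset import BLANKET_ORDER, FinePosture, Manifest, Sample
from .errors import ConfigurationError, InputError, IntegrityError

__all__ = [
    "AffineConfig",
    "FusionPair",
    "FusedSample",
    "apply_affine",
    "affine_augment",
    "fuse",
    "enumerate_fusion_pairs",
    "synthesized_epoch",
]


@dataclass(frozen=True)
class AffineConfig:
    """Bounded random affine transform: range shifts of 5% scale,
    2% translation, 5.0 deg rotation and 2.5 deg shear, chosen so a
    centred body stays fully inside the frame."""

    scale_range: float = 0.05
    translate_range: float = 0.02
    rotate_range: float = 5.0
    shear_range: float = 2.5
    fill_value: float | None = None  # bed-plane depth; rig height when None

    def __post_init__(self):
        for name in ("scale_range", "translate_range", "rotate_range", "shear_range"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


def apply_affine(
    depth: np.ndarray,
    scale: float = 1.0,
    translate: tuple[float, float] = (0.0, 0.0),
    rotate_deg: float = 0.0,
    shear_deg: float = 0.0,
    fill: float = 1600.0,
) -> np.ndarray:
    """Apply one affine transform (about the frame centre) to a depth image.

    ``translate`` is in pixels (row, col).  Out-of-frame regions are
    filled with the bed-plane depth; interpolation is bilinear.
    """
    if scale <= 0:
        raise InputError("zero-area affine transform (scale <= 0)")
    depth = np.asarray(depth)
    theta = math.radians(rotate_deg)
    sh = math.tan(math.radians(shear_deg))
    # forward output<-input mapping pieces, then invert for ndimage
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    shear = np.array([[1.0, sh], [0.0, 1.0]])
    fwd = scale * (rot @ shear)
    inv = np.linalg.inv(fwd)
    centre = (np.asarray(depth.shape, dtype=float) - 1.0) / 2.0
    offset = centre - inv @ (centre + np.asarray(translate, dtype=float))
    out = ndimage.affine_transform(
        depth.astype(float), inv, offset=offset, order=1, mode="constant", cval=fill
    )
    return out.astype(depth.dtype, copy=False)


def affine_augment(
    frame: np.ndarray,
    config: AffineConfig,
    rng: np.random.Generator,
    bed_depth: float = 1600.0,
) -> np.ndarray:
    """Draw one random transform within the configured ranges and apply it."""
    scale = 1.0 + rng.uniform(-config.scale_range, config.scale_range)
    tr = rng.uniform(-config.translate_range, config.translate_range, size=2)
    translate = (tr[0] * frame.shape[0], tr[1] * frame.shape[1])
    rotate = rng.uniform(-config.rotate_range, config.rotate_range)
    shear = rng.uniform(-config.shear_range, config.shear_range)
    fill = config.fill_value if config.fill_value is not None else bed_depth
    return apply_affine(frame, scale, translate, rotate, shear, fill)


# ---------------------------------------------------------------------------
# Blanket fusion


def fuse(frame_a: np.ndarray, frame_b: np.ndarray, u: float) -> np.ndarray:
    """Elementwise convex combination ``u*frame_a + (1-u)*frame_b``."""
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise InputError(f"shape mismatch: {frame_a.shape} vs {frame_b.shape}")
    if not (0.0 <= u <= 1.0):
        raise InputError(f"fusion weight u={u} outside [0, 1]")
    return u * frame_a + (1.0 - u) * frame_b


@dataclass(frozen=True)
class FusionPair:
    """Two samples eligible for fusion: same participant and posture,
    different blanket conditions."""

    sample_a: Sample
    sample_b: Sample
    u: float

    def __post_init__(self):
        a, b = self.sample_a, self.sample_b
        if a.participant_id != b.participant_id or a.fine_label != b.fine_label:
            raise IntegrityError(
                "fusion pair must share participant and fine posture label"
            )
        if a.blanket == b.blanket:
            raise IntegrityError("fusion pair must differ in blanket condition")
        if not (0.0 <= self.u <= 1.0):
            raise InputError(f"fusion weight u={self.u} outside [0, 1]")


def enumerate_fusion_pairs(
    manifest: Manifest, participant_id: str, fine_label: FinePosture
) -> list[tuple[str, str]]:
    """All unordered pairs of distinct blanket conditions available for
    one participant and posture, in canonical order (thick < medium <
    thin < none).  Fewer than two conditions yields an empty list."""
    present = {
        s.blanket
        for s in manifest
        if s.participant_id == participant_id and s.fine_label == fine_label
    }
    ordered = [b for b in BLANKET_ORDER if b in present]
    return list(itertools.combinations(ordered, 2))


@dataclass(frozen=True)
class FusedSample:
    """A synthesized sample under a hypothetical blanket condition."""

    frame: np.ndarray
    participant_id: str
    fine_label: FinePosture
    blanket: str  # "fused(a,b)"
    u: float


def synthesized_epoch(
    manifest: Manifest,
    frames: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> Iterator[FusedSample]:
    """One epoch of the synthesized dataset: one fused sample per
    (participant, posture, condition-pair), each with a fresh
    ``u ~ U(0,1)``.

    With all four conditions present this yields 6 fused samples per
    participant-posture, e.g. 51 x 7 x 6 = 2142 per epoch.  The fused
    sample inherits the (asserted-identical) fine label of its parents.
    """
    index: dict[tuple[str, FinePosture, str], Sample] = {}
    for s in manifest:
        index[(s.participant_id, s.fine_label, s.blanket)] = s
    participants: dict[str, None] = {}
    for s in manifest:
        participants.setdefault(s.participant_id, None)
    for pid in participants:
        for posture in FinePosture:
            for ba, bb in enumerate_fusion_pairs(manifest, pid, posture):
                sa = index[(pid, posture, ba)]
                sb = index[(pid, posture, bb)]
                pair = FusionPair(sa, sb, u=float(rng.uniform()))
                fused = fuse(frames[sa.sample_id], frames[sb.sample_id], pair.u)
                yield FusedSample(
                    frame=fused,
                    participant_id=pid,
                    fine_label=posture,
                    blanket=f"fused({ba},{bb})",
                    u=pair.u,
                )
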