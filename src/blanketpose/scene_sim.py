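"""Synthetic overhead depth scenes of a person in bed, with and without blankets.

The simulator emulates the acquisition geometry of an overhead
time-of-flight depth camera mounted 1.6 m above a 196 x 90 cm bed, looking
straight down.  A body is modelled as a composition of smooth convex
primitives (capsule height fields for head, trunk, arms and legs) posed
by one of seven recumbent-posture templates; a blanket is modelled as a
smoothed, offset copy of the body height field clamped to stay above the
body.  Rendering is orthographic: each pixel stores the camera-to-surface
distance in millimetres, plus truncated Gaussian sensor noise.

Left/right posture variants are generated from a single template whose
lateral coordinates are multiplied by a chirality sign, on a laterally
symmetric pixel grid; before random bed offset/rotation the rendered
pair are therefore exact mirror images.

Per-participant morphometry (stature, shoulder width, trunk thickness,
limb radius, habitual knee flexion...) is drawn from truncated normal
population distributions; the default population has mean stature
167 cm (SD 18 cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataset import BLANKET_ORDER, FinePosture, Manifest, Sample
from .errors import ConfigurationError, GeometryError, LabelError

__all__ = [
    "CameraRig",
    "BodyParams",
    "BlanketCondition",
    "DepthFrame",
    "PopulationConfig",
    "default_population",
    "default_blankets",
    "sample_body_params",
    "pose_body",
    "apply_blanket",
    "render_depth",
    "generate_dataset",
    "SimulatedDataset",
]


# ---------------------------------------------------------------------------
# Geometry


@dataclass(frozen=True)
class CameraRig:
    """Overhead camera + bed geometry.  All lengths in millimetres.

    The rendered field of view is the bed rectangle plus ``margin`` on
    every side; row 0 is the head end of the bed.
    """

    height_above_bed: float = 1600.0
    frame_rows: int = 128
    frame_cols: int = 96
    bed_length: float = 1960.0
    bed_width: float = 900.0
    margin: float = 60.0

    def __post_init__(self):
        if self.height_above_bed <= 0:
            raise ConfigurationError("camera height must be positive")
        if self.frame_rows < 16 or self.frame_cols < 16:
            raise ConfigurationError("frame dimensions must be at least 16")
        if self.bed_length <= 0 or self.bed_width <= 0 or self.margin < 0:
            raise ConfigurationError("bed dimensions must be positive")

    @property
    def fov_length(self) -> float:
        return self.bed_length + 2 * self.margin

    @property
    def fov_width(self) -> float:
        return self.bed_width + 2 * self.margin

    @property
    def pitch(self) -> tuple[float, float]:
        """(row, col) pixel pitch in mm."""
        return self.fov_length / self.frame_rows, self.fov_width / self.frame_cols

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates: x along the bed from the head end
        (shape ``(rows, 1)``), y lateral from the bed midline (shape
        ``(1, cols)``).  The y axis is forced to be exactly antisymmetric
        so that mirrored bodies render to exactly mirrored frames.
        """
        pr, pc = self.pitch
        x = (np.arange(self.frame_rows) + 0.5) * pr - self.margin
        y = (np.arange(self.frame_cols) + 0.5) * pc - self.fov_width / 2.0
        y = (y - y[::-1]) / 2.0  # enforce exact lateral antisymmetry
        return x[:, None], y[None, :]


@dataclass(frozen=True)
class DepthFrame:
    """A rendered depth image: per-pixel camera-to-surface distance in mm."""

    depth: np.ndarray
    rig: CameraRig

    def __post_init__(self):
        d = self.depth
        if d.ndim != 2:
            raise GeometryError("depth frame must be 2-D")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise GeometryError("depth values must be finite and positive")
        ceiling = self.rig.height_above_bed + 200.0  # bed plane + noise margin
        if np.any(d > ceiling):
            raise GeometryError("depth exceeds the camera-to-bed distance margin")


# ---------------------------------------------------------------------------
# Population / morphometry


@dataclass(frozen=True)
class TruncatedNormal:
    """Mean/SD with hard physical bounds; SD 0 collapses to the mean."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigurationError("SD must be non-negative")
        if not (self.low <= self.mean <= self.high):
            raise ConfigurationError(
                f"mean {self.mean} outside physical bounds [{self.low}, {self.high}]"
            )

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        for _ in range(1000):
            v = rng.normal(self.mean, self.sd)
            if self.low <= v <= self.high:
                return float(v)
        raise ConfigurationError("truncated-normal rejection failed; check bounds")


@dataclass(frozen=True)
class PopulationConfig:
    """Per-field morphometric distributions (cm / degrees)."""

    stature: TruncatedNormal = TruncatedNormal(167.0, 18.0, 145.0, 190.0)
    shoulder_width: TruncatedNormal = TruncatedNormal(41.0, 4.0, 34.0, 52.0)
    trunk_thickness: TruncatedNormal = TruncatedNormal(23.0, 3.0, 16.0, 28.0)
    limb_radius: TruncatedNormal = TruncatedNormal(5.5, 0.8, 4.0, 7.5)
    knee_flexion: TruncatedNormal = TruncatedNormal(110.0, 15.0, 60.0, 150.0)
    head_yaw: TruncatedNormal = TruncatedNormal(55.0, 10.0, 30.0, 80.0)
    bed_offset: TruncatedNormal = TruncatedNormal(0.0, 3.0, -8.0, 8.0)
    bed_rotation: TruncatedNormal = TruncatedNormal(0.0, 2.0, -6.0, 6.0)


def default_population() -> PopulationConfig:
    return PopulationConfig()


@dataclass(frozen=True)
class BodyParams:
    """One participant's morphometry.  Lengths in cm, angles in degrees."""

    stature: float
    shoulder_width: float
    trunk_thickness: float
    limb_radius: float
    knee_flexion: float
    head_yaw: float
    bed_offset: tuple[float, float]
    bed_rotation: float

    def __post_init__(self):
        if self.stature <= 0:
            raise ConfigurationError("stature must be positive")
        if not (0.0 <= self.knee_flexion <= 150.0):
            raise ConfigurationError("knee flexion must lie in [0, 150] degrees")


def sample_body_params(
    rng: np.random.Generator, population: PopulationConfig | None = None
) -> BodyParams:
    """Draw one participant's morphometry from the population model.

    Draws are truncated normals; a fixed generator state reproduces the
    same sequence of bodies.
    """
    pop = population or default_population()
    return BodyParams(
        stature=pop.stature.draw(rng),
        shoulder_width=pop.shoulder_width.draw(rng),
        trunk_thickness=pop.trunk_thickness.draw(rng),
        limb_radius=pop.limb_radius.draw(rng),
        knee_flexion=pop.knee_flexion.draw(rng),
        head_yaw=pop.head_yaw.draw(rng),
        bed_offset=(pop.bed_offset.draw(rng), pop.bed_offset.draw(rng)),
        bed_rotation=pop.bed_rotation.draw(rng),
    )


# ---------------------------------------------------------------------------
# Blankets


@dataclass(frozen=True)
class BlanketCondition:
    """A blanket: name, loft thickness, and drape smoothing scale (mm)."""

    name: str
    thickness: float
    drape_smoothing: float

    def __post_init__(self):
        if self.thickness < 0:
            raise ConfigurationError("blanket thickness must be non-negative")
        if self.drape_smoothing < 0:
            raise ConfigurationError("drape smoothing must be non-negative")


def default_blankets() -> dict[str, BlanketCondition]:
    """The four study conditions: 8 cm, 2 cm, 0.4 cm, and no blanket.

    Drape smoothing grows with thickness: a loftier blanket bridges
    concavities over a longer length scale.
    """
    return {
        "thick": BlanketCondition("thick", 80.0, 60.0),
        "medium": BlanketCondition("medium", 20.0, 30.0),
        "thin": BlanketCondition("thin", 4.0, 12.0),
        "none": BlanketCondition("none", 0.0, 0.0),
    }


# ---------------------------------------------------------------------------
# Posing


def _capsule(
    X: np.ndarray,
    Y: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    radius: float,
    height: float,
) -> np.ndarray:
    """Height field of a capsule lying on the bed plane.

    Elliptical cross-section: ``h * sqrt(1 - (d/r)^2)`` where *d* is the
    in-plane distance to the axis segment p0-p1 (all mm).
    """
    ax, ay = p0
    bx, by = p1
    vx, vy = bx - ax, by - ay
    vv = vx * vx + vy * vy
    if vv == 0.0:
        dx, dy = X - ax, Y - ay
    else:
        t = np.clip(((X - ax) * vx + (Y - ay) * vy) / vv, 0.0, 1.0)
        dx = X - (ax + t * vx)
        dy = Y - (ay + t * vy)
    d2 = dx * dx + dy * dy
    arg = 1.0 - d2 / (radius * radius)
    return height * np.sqrt(np.clip(arg, 0.0, None))


def _template_primitives(
    params: BodyParams, posture: FinePosture, jitter: float
) -> list[tuple[tuple[float, float], tuple[float, float], float, float]]:
    """Capsule list ``(p0, p1, radius, height)`` in body coordinates (mm).

    x runs head-to-foot from the top of the head; y is lateral with the
    template's chirality sign already applied.
    """
    s = params.stature * 10.0  # mm
    sw = params.shoulder_width * 10.0
    tt = params.trunk_thickness * 10.0
    lr = params.limb_radius * 10.0

    name = posture.name
    prims: list[tuple[tuple[float, float], tuple[float, float], float, float]] = []

    if name == "supine" or name.startswith("prone"):
        prone = name.startswith("prone")
        m = 1.0 if name.endswith("left") else -1.0
        # head: straight capsule when supine, yawed to one side when prone
        if prone:
            yaw = math.radians(params.head_yaw)
            h0 = (0.035 * s, 0.0)
            h1 = (0.035 * s + 0.07 * s * math.cos(yaw), m * 0.07 * s * math.sin(yaw))
            prims.append((h0, h1, 0.045 * s, 0.62 * tt))
        else:
            prims.append(((0.02 * s, 0.0), (0.10 * s, 0.0), 0.045 * s, 0.85 * tt))
        # trunk: chest + pelvis
        prims.append(((0.14 * s, 0.0), (0.30 * s, 0.0), 0.5 * sw, (0.95 if prone else 1.0) * tt))
        prims.append(((0.30 * s, 0.0), (0.46 * s, 0.0), 0.42 * sw, (1.0 if prone else 0.95) * tt))
        for q in (1.0, -1.0):
            if prone:
                # arms raised beside the head
                prims.append(
                    (
                        (0.17 * s, q * (0.5 * sw + 0.6 * lr)),
                        (0.06 * s, q * (0.5 * sw + 1.6 * lr)),
                        lr,
                        2.0 * lr,
                    )
                )
            else:
                # arms along the sides
                prims.append(
                    (
                        (0.16 * s, q * (0.5 * sw + 0.8 * lr)),
                        (0.44 * s, q * (0.40 * sw + lr)),
                        lr,
                        2.0 * lr,
                    )
                )
            # legs: thigh, shank, feet
            prims.append(
                ((0.46 * s, q * 0.15 * sw), (0.72 * s, q * 0.12 * sw), 1.3 * lr, 2.6 * lr)
            )
            prims.append(
                ((0.72 * s, q * 0.12 * sw), (0.955 * s, q * 0.11 * sw), lr, 2.0 * lr)
            )
            foot_h = 1.2 * lr if prone else 3.0 * lr  # toes up when supine
            prims.append(
                ((0.955 * s, q * 0.11 * sw), (0.985 * s, q * 0.11 * sw), 1.1 * lr, foot_h)
            )
        return prims

    if name.startswith(("log", "fetal")):
        fetal = name.startswith("fetal")
        m = 1.0 if name.endswith("left") else -1.0
        # side-lying stack height: half shoulder breadth + half chest depth
        trunk_h = 0.5 * (sw + tt)
        prims.append(((0.03 * s, 0.0), (0.10 * s, m * 0.01 * s), 0.04 * s, 0.72 * trunk_h))
        prims.append(((0.13 * s, 0.0), (0.45 * s, m * 0.02 * s), 0.55 * tt, trunk_h))
        # both arms folded in front of the chest (stacked)
        prims.append(
            (
                (0.17 * s, m * (0.55 * tt + 0.5 * lr)),
                (0.36 * s, m * (0.55 * tt + 2.2 * lr)),
                1.2 * lr,
                0.55 * trunk_h,
            )
        )
        hip = (0.47 * s, m * 0.015 * s)
        if fetal:
            alpha = math.radians(30.0 + jitter)
            knee_flex = math.radians(params.knee_flexion)
        else:
            alpha = math.radians(10.0 + jitter)
            knee_flex = math.radians(0.25 * params.knee_flexion)
        thigh_len, shank_len = 0.24 * s, 0.22 * s
        knee = (
            hip[0] + thigh_len * math.cos(alpha),
            hip[1] + m * thigh_len * math.sin(alpha),
        )
        beta = alpha - knee_flex
        foot = (
            knee[0] + shank_len * math.cos(beta),
            knee[1] + m * shank_len * math.sin(beta),
        )
        # stacked legs rendered as one thick pair
        prims.append((hip, knee, 1.7 * lr, 0.50 * trunk_h))
        prims.append((knee, foot, 1.35 * lr, 0.42 * trunk_h))
        return prims

    raise LabelError(f"unknown posture: {posture!r}")


def pose_body(
    params: BodyParams,
    posture: FinePosture | int,
    rig: CameraRig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a posed body as a height field over the bed plane (mm).

    The body is the pointwise maximum of the template's capsule height
    fields, rotated by the participant's bed rotation and translated by
    their bed offset.  Fetal templates use the participant's full
    habitual knee flexion, log templates a quarter of it, so fetal knees
    are always more flexed than log knees for the same body.  An
    optional ``rng`` adds a small limb-angle jitter (one draw), so that
    a fixed generator state freezes the pose.
    """
    try:
        posture = FinePosture(posture)
    except ValueError as exc:
        raise LabelError(f"unknown posture label: {posture!r}") from exc
    rig = rig or CameraRig()
    jitter = float(rng.uniform(-4.0, 4.0)) if rng is not None else 0.0
    prims = _template_primitives(params, posture, jitter)

    s = params.stature * 10.0
    start_x = (rig.bed_length - s) / 2.0 + params.bed_offset[0] * 10.0
    off_y = params.bed_offset[1] * 10.0
    rot = math.radians(params.bed_rotation)
    cx, cy = 0.5 * s, 0.0  # rotate about body centre

    # clamp the random offset so the body footprint stays on the bed
    y_extent = max(max(abs(p0[1]), abs(p1[1])) + r for p0, p1, r, _ in prims)
    y_slack = max(rig.bed_width / 2.0 - y_extent, 0.0)
    off_y = float(np.clip(off_y, -y_slack, y_slack))
    x_lo = min(min(p0[0], p1[0]) - r for p0, p1, r, _ in prims)
    x_hi = max(max(p0[0], p1[0]) + r for p0, p1, r, _ in prims)
    start_x = float(np.clip(start_x, -x_lo, rig.bed_length - x_hi))

    def place(p: tuple[float, float]) -> tuple[float, float]:
        x, y = p[0] - cx, p[1] - cy
        if rot != 0.0:
            x, y = x * math.cos(rot) - y * math.sin(rot), x * math.sin(rot) + y * math.cos(rot)
        return x + cx + start_x, y + off_y

    X, Y = rig.grid()
    surface = np.zeros((rig.frame_rows, rig.frame_cols))
    for p0, p1, r, h in prims:
        np.maximum(surface, _capsule(X, Y, place(p0), place(p1), r, h), out=surface)
    return surface


# ---------------------------------------------------------------------------
# Blanket drape


#: Blanket coverage along the bed: bare above ``_COVER_START`` mm from the
#: head end (head and shoulders exposed), fully covered below
#: ``_COVER_FULL``, cosine-feathered in between.
_COVER_START = 430.0
_COVER_FULL = 530.0


def apply_blanket(
    body_surface: np.ndarray,
    blanket: BlanketCondition,
    rig: CameraRig | None = None,
) -> np.ndarray:
    """Drape a blanket over a body height field.

    The draped surface is a Gaussian-smoothed copy of the body raised by
    the blanket thickness and clamped to stay at or above the body; the
    head end of the bed is left uncovered with a feathered edge.  The
    ``none`` condition returns the input unchanged.  A loftier blanket
    (larger drape smoothing) bridges body concavities over a longer
    length scale, acting as a low-pass filter on surface detail.
    """
    body_surface = np.asarray(body_surface, dtype=float)
    if not np.all(np.isfinite(body_surface)) or np.any(body_surface < 0):
        raise GeometryError("body surface must be finite and non-negative")
    if blanket.thickness == 0 and blanket.drape_smoothing == 0:
        return body_surface
    rig = rig or CameraRig()
    pr, pc = rig.pitch
    sigma = (blanket.drape_smoothing / pr, blanket.drape_smoothing / pc)
    smoothed = ndimage.gaussian_filter(body_surface, sigma=sigma, mode="nearest")
    draped = np.maximum(smoothed + blanket.thickness, body_surface)

    x = rig.grid()[0][:, 0]
    w = np.clip((x - _COVER_START) / (_COVER_FULL - _COVER_START), 0.0, 1.0)
    w = 0.5 - 0.5 * np.cos(np.pi * w)  # cosine feather
    return body_surface + w[:, None] * (draped - body_surface)


# ---------------------------------------------------------------------------
# Rendering


def render_depth(
    covered_surface: np.ndarray,
    rig: CameraRig | None = None,
    noise_sd: float = 5.0,
    rng: np.random.Generator | None = None,
) -> DepthFrame:
    """Convert a surface height field to a depth frame.

    ``depth = camera height - surface height``, plus zero-mean Gaussian
    sensor noise truncated at +-3 SD.  An empty bed with zero noise
    renders as a constant frame at the camera-to-mattress distance.
    """
    rig = rig or CameraRig()
    surface = np.asarray(covered_surface, dtype=float)
    if np.any(surface >= rig.height_above_bed):
        raise GeometryError("surface penetrates the camera plane")
    depth = rig.height_above_bed - surface
    if noise_sd < 0:
        raise ConfigurationError("noise SD must be non-negative")
    if noise_sd > 0:
        if rng is None:
            raise ConfigurationError("noisy rendering requires a seeded generator")
        noise = rng.normal(0.0, noise_sd, size=depth.shape)
        np.clip(noise, -3.0 * noise_sd, 3.0 * noise_sd, out=noise)
        depth = depth + noise
    return DepthFrame(depth=depth, rig=rig)


# ---------------------------------------------------------------------------
# Dataset generation


@dataclass
class SimulatedDataset:
    """A generated cohort: manifest, rendered frames, and pre-blanket bodies."""

    manifest: Manifest
    frames: dict[str, np.ndarray]
    body_surfaces: dict[tuple[str, FinePosture], np.ndarray]
    rig: CameraRig

    def frame(self, sample: Sample) -> np.ndarray:
        return self.frames[sample.sample_id]


def generate_dataset(
    n_participants: int,
    seed: int,
    rig: CameraRig | None = None,
    blankets: dict[str, BlanketCondition] | None = None,
    noise_sd: float = 5.0,
    population: PopulationConfig | None = None,
) -> SimulatedDataset:
    """Simulate a full cohort: every participant performs every posture
    under every blanket condition.

    For a given participant and posture the body pose is rendered once
    and reused across all blanket conditions — the premise that makes
    intraclass blanket fusion physically meaningful.  51 participants
    under the 4 standard conditions yield 51 x 7 x 4 = 1428 samples.
    All randomness derives from ``seed``.
    """
    if n_participants < 1:
        raise ConfigurationError("need at least one participant")
    rig = rig or CameraRig()
    blankets = blankets if blankets is not None else default_blankets()
    order = [b for b in BLANKET_ORDER if b in blankets]
    rng = np.random.default_rng(seed)

    samples: list[Sample] = []
    frames: dict[str, np.ndarray] = {}
    bodies: dict[tuple[str, FinePosture], np.ndarray] = {}
    for p in range(n_participants):
        pid = f"P{p:03d}"
        params = sample_body_params(rng, population)
        for posture in FinePosture:
            pose_rng = np.random.default_rng(rng.integers(0, 2**31))
            body = pose_body(params, posture, rig, pose_rng)
            bodies[(pid, posture)] = body
            for bname in order:
                covered = apply_blanket(body, blankets[bname], rig)
                frame = render_depth(covered, rig, noise_sd, rng)
                sid = f"{pid}_{posture.name}_{bname}"
                frames[sid] = frame.depth.astype(np.float32)
                samples.append(
                    Sample(
                        sample_id=sid,
                        participant_id=pid,
                        fine_label=posture,
                        blanket=bname,
                    )
                )
    manifest = Manifest(
        samples=samples,
        metadata={"seed": seed, "n_participants": n_participants, "noise_sd": noise_sd},
    )
    return SimulatedDataset(manifest=manifest, frames=frames, body_surfaces=bodies, rig=rig)
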