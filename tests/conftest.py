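import numpy as np
import pytest

from blanketpose.scene_sim import (
    BodyParams,
    CameraRig,
    generate_dataset,
    sample_body_params,
)


@pytest.fixture(scope="session")
def small_rig() -> CameraRig:
    """Desk-scale rig at reduced resolution for fast tests."""
    return CameraRig(frame_rows=64, frame_cols=48)


@pytest.fixture(scope="session")
def mean_body() -> BodyParams:
    """A deterministic average participant, centred on the bed."""
    return BodyParams(
        stature=167.0,
        shoulder_width=41.0,
        trunk_thickness=23.0,
        limb_radius=5.5,
        knee_flexion=110.0,
        head_yaw=55.0,
        bed_offset=(0.0, 0.0),
        bed_rotation=0.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort(small_rig):
    """3 participants x 7 postures x 4 blankets = 84 samples."""
    return generate_dataset(3, seed=7, rig=small_rig)


@pytest.fixture(scope="session")
def sampled_bodies():
    rng = np.random.default_rng(99)
    return [sample_body_params(rng) for _ in range(20)]
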