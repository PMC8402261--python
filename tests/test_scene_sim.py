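"""Scene simulator: population sampling, posing, blanket drape, rendering."""

from dataclasses import replace

import numpy as np
import pytest

from blanketpose.dataset import FinePosture, coarse_from_fine
from blanketpose.errors import ConfigurationError, GeometryError, LabelError
from blanketpose.scene_sim import (
    BlanketCondition,
    CameraRig,
    PopulationConfig,
    TruncatedNormal,
    apply_blanket,
    default_blankets,
    generate_dataset,
    pose_body,
    render_depth,
    sample_body_params,
)


def total_variation(a: np.ndarray) -> float:
    return float(np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum())


# ---------------------------------------------------------------------------
# sample_body_params


class TestBodySampling:
    def test_long_run_stature_mean_matches_population(self):
        """Over 10,000 draws the sample mean stature lands within 3
        standard errors of the configured 167 cm population mean."""
        rng = np.random.default_rng(0)
        draws = np.array([sample_body_params(rng).stature for _ in range(10_000)])
        se = 18.0 / np.sqrt(len(draws))
        assert abs(draws.mean() - 167.0) < 3 * se

    def test_zero_variance_population_is_deterministic(self):
        pop = PopulationConfig(
            stature=TruncatedNormal(167.0, 0.0, 145.0, 190.0),
            shoulder_width=TruncatedNormal(41.0, 0.0, 34.0, 52.0),
            trunk_thickness=TruncatedNormal(23.0, 0.0, 16.0, 28.0),
            limb_radius=TruncatedNormal(5.5, 0.0, 4.0, 7.5),
            knee_flexion=TruncatedNormal(110.0, 0.0, 60.0, 150.0),
            head_yaw=TruncatedNormal(55.0, 0.0, 30.0, 80.0),
            bed_offset=TruncatedNormal(0.0, 0.0, -8.0, 8.0),
            bed_rotation=TruncatedNormal(0.0, 0.0, -6.0, 6.0),
        )
        rng = np.random.default_rng(1)
        draws = [sample_body_params(rng, pop) for _ in range(5)]
        assert all(d == draws[0] for d in draws)
        assert draws[0].stature == 167.0

    def test_knee_flexion_mean_matches_independent_redraw(self):
        """Monte-Carlo oracle: the mean of 10,000 seeded knee-flexion draws
        agrees (within 3 SE) with a direct truncated-normal re-draw using
        the same generator parameters."""
        pop = PopulationConfig()
        rng = np.random.default_rng(42)
        draws = np.array([sample_body_params(rng).knee_flexion for _ in range(10_000)])

        # independent re-draw: plain rejection sampling of the same law
        rng2 = np.random.default_rng(2024)
        tn = pop.knee_flexion
        ref = []
        while len(ref) < 10_000:
            v = rng2.normal(tn.mean, tn.sd, size=1000)
            ref.extend(v[(v >= tn.low) & (v <= tn.high)])
        ref = np.array(ref[:10_000])
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - ref.mean()) < 3 * se

    def test_same_seed_reproduces_sequence(self):
        a = [sample_body_params(np.random.default_rng(5)) for _ in range(3)]
        b = [sample_body_params(np.random.default_rng(5)) for _ in range(3)]
        assert a == b

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            TruncatedNormal(167.0, -1.0, 145.0, 190.0)

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            TruncatedNormal(200.0, 5.0, 145.0, 190.0)


# ---------------------------------------------------------------------------
# pose_body


class TestPoseBody:
    def test_fetal_knee_flexion_exceeds_log(self, mean_body):
        """Fetal templates use the participant's full knee flexion, log a
        quarter of it — the fetal 'cuddle' is always more flexed."""
        assert mean_body.knee_flexion > 0.25 * mean_body.knee_flexion
        # geometric consequence: fetal legs are drawn in, shortening the
        # body footprint along the bed compared to the extended log pose
        rig = CameraRig(frame_rows=64, frame_cols=48)
        log = pose_body(mean_body, FinePosture.log_left, rig)
        fetal = pose_body(mean_body, FinePosture.fetal_left, rig)
        extent = lambda s: np.nonzero((s > 10).any(axis=1))[0].max()
        assert extent(fetal) < extent(log)

    @pytest.mark.parametrize(
        "left,right",
        [
            (FinePosture.log_left, FinePosture.log_right),
            (FinePosture.fetal_left, FinePosture.fetal_right),
            (FinePosture.prone_head_left, FinePosture.prone_head_right),
        ],
    )
    def test_left_right_templates_are_exact_mirrors(self, mean_body, small_rig, left, right):
        l = pose_body(mean_body, left, small_rig)
        r = pose_body(mean_body, right, small_rig)
        assert np.array_equal(l[:, ::-1], r)

    def test_side_lying_taller_than_supine(self, small_rig, sampled_bodies):
        """Shoulder stack-up: every side-lying pose peaks higher than the
        supine pose of the same body (20 seeded bodies)."""
        for body in sampled_bodies:
            sup = pose_body(body, FinePosture.supine, small_rig)
            side = pose_body(body, FinePosture.log_left, small_rig)
            assert side.max() > sup.max()

    def test_unknown_posture_rejected(self, mean_body, small_rig):
        with pytest.raises(LabelError):
            pose_body(mean_body, 42, small_rig)

    def test_body_footprint_inside_bed(self, small_rig, sampled_bodies):
        """Random offsets are clamped so the body never leaves the bed
        rectangle (the margin pixels beyond the bed stay empty)."""
        pr, pc = small_rig.pitch
        mrows = int(np.ceil(small_rig.margin / pr))
        mcols = int(np.ceil(small_rig.margin / pc))
        for body in sampled_bodies[:8]:
            for posture in FinePosture:
                s = pose_body(body, posture, small_rig)
                assert s[:mrows].max() < 1.0 and s[-mrows:].max() < 1.0
                assert s[:, :mcols].max() < 1.0 and s[:, -mcols:].max() < 1.0


# ---------------------------------------------------------------------------
# apply_blanket


class TestApplyBlanket:
    def test_none_is_identity(self, mean_body, small_rig):
        body = pose_body(mean_body, FinePosture.supine, small_rig)
        out = apply_blanket(body, default_blankets()["none"], small_rig)
        assert np.array_equal(out, body)

    @pytest.mark.parametrize("name", ["thick", "medium", "thin"])
    def test_covered_surface_at_or_above_body(self, mean_body, small_rig, name):
        body = pose_body(mean_body, FinePosture.fetal_right, small_rig)
        out = apply_blanket(body, default_blankets()[name], small_rig)
        assert np.all(out >= body - 1e-9)

    def test_total_variation_nonincreasing_in_smoothing(self, mean_body, small_rig):
        body = pose_body(mean_body, FinePosture.supine, small_rig)
        tvs = [
            total_variation(apply_blanket(body, BlanketCondition("thick", 80.0, sm), small_rig))
            for sm in (20.0, 60.0, 120.0)
        ]
        assert tvs[0] >= tvs[1] >= tvs[2]

    def test_negative_thickness_rejected(self):
        with pytest.raises(ConfigurationError):
            BlanketCondition("bad", -1.0, 10.0)

    def test_default_blankets_ordering(self):
        b = default_blankets()
        assert b["thick"].thickness == 80.0 > b["medium"].thickness == 20.0
        assert b["medium"].thickness > b["thin"].thickness == 4.0 > b["none"].thickness == 0.0
        assert (
            b["thick"].drape_smoothing
            >= b["medium"].drape_smoothing
            >= b["thin"].drape_smoothing
            >= b["none"].drape_smoothing
        )


# ---------------------------------------------------------------------------
# render_depth


class TestRenderDepth:
    def test_empty_bed_zero_noise_is_constant_at_camera_height(self, small_rig):
        frame = render_depth(np.zeros((64, 48)), small_rig, noise_sd=0.0)
        assert np.all(frame.depth == small_rig.height_above_bed)

    def test_blanket_never_increases_depth(self, mean_body, small_rig):
        body = pose_body(mean_body, FinePosture.log_left, small_rig)
        covered = apply_blanket(body, default_blankets()["thick"], small_rig)
        d_bare = render_depth(body, small_rig, 0.0).depth
        d_cov = render_depth(covered, small_rig, 0.0).depth
        assert np.all(d_cov <= d_bare + 1e-9)

    def test_noise_sd_calibration(self, mean_body, small_rig):
        """Per-cell sample SD over 200 seeded renders of a fixed scene is
        within 10% of the configured 5 mm (Monte-Carlo oracle)."""
        body = pose_body(mean_body, FinePosture.supine, small_rig)
        rng = np.random.default_rng(3)
        stack = np.stack(
            [render_depth(body, small_rig, 5.0, rng).depth for _ in range(200)]
        )
        per_cell_sd = stack.std(axis=0)
        assert abs(per_cell_sd.mean() - 5.0) < 0.5

    def test_surface_at_camera_plane_rejected(self, small_rig):
        with pytest.raises(GeometryError):
            render_depth(np.full((64, 48), 1700.0), small_rig, 0.0)


# ---------------------------------------------------------------------------
# generate_dataset


class TestGenerateDataset:
    def test_one_participant_gives_28_samples(self, small_rig):
        data = generate_dataset(1, seed=0, rig=small_rig)
        assert len(data.manifest) == 1 * 7 * 4 == 28

    def test_pose_frozen_across_blanket_conditions(self, tiny_cohort):
        """The stored pre-blanket body surface is shared by all four
        conditions of a (participant, posture): re-deriving it from the
        no-blanket frame's noise-free counterpart matches exactly."""
        data = tiny_cohort
        for (pid, posture), body in data.body_surfaces.items():
            # all four frames of this cell were rendered from this body
            frames = [
                data.frames[s.sample_id]
                for s in data.manifest
                if s.participant_id == pid and s.fine_label == posture
            ]
            assert len(frames) == 4
            # the noise-free depth implied by the body bounds every frame
            # within the 3-sigma noise truncation
            base = data.rig.height_above_bed - body
            for f, s in zip(
                frames,
                [
                    s
                    for s in data.manifest
                    if s.participant_id == pid and s.fine_label == posture
                ],
            ):
                if s.blanket == "none":
                    assert np.all(np.abs(f - base) <= 3 * 5.0 + 1e-3)

    def test_determinism_bit_identical(self, small_rig):
        a = generate_dataset(2, seed=11, rig=small_rig)
        b = generate_dataset(2, seed=11, rig=small_rig)
        assert a.manifest.to_frame().equals(b.manifest.to_frame())
        for sid in a.frames:
            assert np.array_equal(a.frames[sid], b.frames[sid])

    def test_geometry_bounds(self, tiny_cohort):
        """Depth stays within [camera height - max body - thick blanket,
        camera height + 3 noise SD]."""
        rig = tiny_cohort.rig
        floor = rig.height_above_bed - (0.5 * (520 + 280) + 80 + 80)  # tallest body + blanket
        ceiling = rig.height_above_bed + 3 * 5.0
        for f in tiny_cohort.frames.values():
            assert f.min() >= floor
            assert f.max() <= ceiling + 1e-6

    def test_coarse_classes_separable_by_nearest_centroid(self, small_rig):
        """Fixture learnability: a nearest-centroid classifier on
        downsampled no-blanket frames beats 4-class chance by a wide
        margin on 20 seeded participants."""
        data = generate_dataset(20, seed=21, rig=small_rig)
        samples = [s for s in data.manifest if s.blanket == "none"]
        X = np.stack([data.frames[s.sample_id][::4, ::4].ravel() for s in samples])
        y = np.array([int(coarse_from_fine(s.fine_label)) for s in samples])
        # leave-participant-out nearest centroid
        pids = np.array([s.participant_id for s in samples])
        correct = 0
        for pid in np.unique(pids):
            train, test = pids != pid, pids == pid
            cents = np.stack([X[train][y[train] == c].mean(axis=0) for c in range(4)])
            d = ((X[test][:, None, :] - cents[None]) ** 2).sum(axis=2)
            correct += (d.argmin(axis=1) == y[test]).sum()
        acc = correct / len(y)
        assert acc > 0.25

    def test_zero_participants_rejected(self, small_rig):
        with pytest.raises(ConfigurationError):
            generate_dataset(0, seed=0, rig=small_rig)
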