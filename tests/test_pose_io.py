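import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posestatics import (
    CalibrationConfig,
    DegenerateSegmentError,
    InsufficientKeypointsError,
    NoSupportError,
    RawPose,
    SceneParams,
    calibrate,
    estimate_scale,
    generate,
    read_pose_file,
    select_person,
    write_pose_file,
)
from posestatics.pose_io import (
    L_ANKLE, L_KNEE, N_KEYPOINTS, R_ANKLE, R_KNEE,
)


def _person(flat):
    return {"version": 1.3, "people": [{"pose_keypoints_2d": flat}]}


def _blank_raw():
    kp = np.zeros((N_KEYPOINTS, 3))
    return kp


class TestReadPoseFile:
    def test_single_person(self, tmp_path):
        path = tmp_path / "pose.json"
        path.write_text(json.dumps(_person([0.0] * 75)))
        poses = read_pose_file(path)
        assert len(poses) == 1
        assert poses[0].keypoints.shape == (25, 3)

    def test_zero_people_is_empty_list(self, tmp_path):
        path = tmp_path / "pose.json"
        path.write_text(json.dumps({"version": 1.3, "people": []}))
        assert read_pose_file(path) == []

    def test_wrong_count_is_parse_error(self, tmp_path):
        from posestatics import ParseError

        path = tmp_path / "pose.json"
        path.write_text(json.dumps(_person([0.0] * 74)))
        with pytest.raises(ParseError):
            read_pose_file(path)

    def test_malformed_json(self, tmp_path):
        from posestatics import ParseError

        path = tmp_path / "pose.json"
        path.write_text("{not json")
        with pytest.raises(ParseError):
            read_pose_file(path)

    def test_round_trip_with_writer(self, tmp_path, readiness_scene):
        path = tmp_path / "pose.json"
        write_pose_file(readiness_scene, path, render=100.0, image_height=1000.0)
        poses = read_pose_file(path)
        assert len(poses) == 1
        hind_ankle = readiness_scene.posture.hind.ankle
        # hind leg maps to the right-side keypoints
        np.testing.assert_allclose(
            poses[0].point(R_ANKLE),
            [hind_ankle[0] * 100.0, 1000.0 - hind_ankle[1] * 100.0],
            atol=1e-9,
        )

    def test_select_person_highest_confidence(self):
        kp_lo, kp_hi = _blank_raw(), _blank_raw()
        kp_lo[:, 2] = 0.2
        kp_hi[:, 2] = 0.9
        best = select_person([RawPose(kp_lo, "a"), RawPose(kp_hi, "b")])
        assert best.source_id == "b"

    def test_select_person_empty(self):
        with pytest.raises(InsufficientKeypointsError):
            select_person([])


class TestEstimateScale:
    def test_forced_ratio(self, default_model):
        kp = _blank_raw()
        kp[R_KNEE] = [0, 0, 1]
        kp[R_ANKLE] = [0, 48, 1]
        assert estimate_scale(RawPose(kp), default_model) == pytest.approx(0.01)

    def test_mean_over_both_legs(self, default_model):
        kp = _blank_raw()
        kp[R_KNEE] = [0, 0, 1]
        kp[R_ANKLE] = [0, 48, 1]
        kp[L_KNEE] = [10, 0, 1]
        kp[L_ANKLE] = [10, 50, 1]
        expected = 0.5 * (0.48 / 48 + 0.48 / 50)
        assert estimate_scale(RawPose(kp), default_model) == pytest.approx(expected)

    def test_coincident_knee_ankle(self, default_model):
        kp = _blank_raw()
        kp[R_KNEE] = [5, 5, 1]
        kp[R_ANKLE] = [5, 5, 1]
        with pytest.raises(DegenerateSegmentError):
            estimate_scale(RawPose(kp), default_model)

    def test_no_valid_leg(self, default_model):
        with pytest.raises(InsufficientKeypointsError):
            estimate_scale(RawPose(_blank_raw()), default_model)


class TestCalibrate:
    def test_round_trip_recovers_world_coordinates(
        self, tmp_path, readiness_scene, default_model
    ):
        path = tmp_path / "pose.json"
        write_pose_file(readiness_scene, path, render=100.0, image_height=800.0)
        raw = select_person(read_pose_file(path))
        posture = calibrate(raw, default_model)
        for side in ("hind", "front"):
            for attr in ("hip", "knee", "ankle", "heel", "toe"):
                np.testing.assert_allclose(
                    getattr(posture.leg(side), attr),
                    getattr(readiness_scene.posture.leg(side), attr),
                    atol=1e-9,
                )
        np.testing.assert_allclose(
            posture.trunk_anchor, readiness_scene.posture.trunk_anchor, atol=1e-9
        )
        assert posture.support_state == "double"

    def test_pure_y_negation_round_trip(self, tmp_path, readiness_scene, default_model):
        path = tmp_path / "pose.json"
        write_pose_file(readiness_scene, path, render=1.0, image_height=0.0)
        raw = select_person(read_pose_file(path))
        posture = calibrate(raw, default_model, CalibrationConfig(scale_m_per_px=1.0))
        np.testing.assert_allclose(
            posture.hind.ankle, readiness_scene.posture.hind.ankle, atol=1e-9
        )

    def test_missing_ankle_confidence(self, tmp_path, readiness_scene, default_model):
        path = tmp_path / "pose.json"
        write_pose_file(readiness_scene, path)
        raw = select_person(read_pose_file(path))
        kp = raw.keypoints.copy()
        kp[R_ANKLE, 2] = 0.0
        with pytest.raises(InsufficientKeypointsError):
            calibrate(RawPose(kp), default_model)

    def test_both_feet_off_ground(self, tmp_path, readiness_scene, default_model):
        path = tmp_path / "pose.json"
        write_pose_file(readiness_scene, path, render=100.0, image_height=800.0)
        raw = select_person(read_pose_file(path))
        kp = raw.keypoints.copy()
        # lift every foot keypoint far above the lowest point (the ground
        # line re-anchors, so spread the feet vertically instead)
        from posestatics.pose_io import L_BIG_TOE, L_HEEL, R_BIG_TOE, R_HEEL

        kp[[R_HEEL, R_BIG_TOE], 1] -= 50.0  # right foot 0.5 m up
        kp[[L_HEEL], 1] -= 30.0  # left heel up, toe stays: neither grounded
        with pytest.raises(NoSupportError):
            calibrate(RawPose(kp), default_model)

    def test_single_support_detected(self, tmp_path, kick_scene, default_model):
        path = tmp_path / "pose.json"
        write_pose_file(kick_scene, path)
        raw = select_person(read_pose_file(path))
        posture = calibrate(raw, default_model)
        assert posture.support_state == "single_hind"

    def test_forced_double_tolerates_small_discrepancy(
        self, tmp_path, readiness_scene, default_model
    ):
        from posestatics.pose_io import L_BIG_TOE, L_HEEL

        path = tmp_path / "pose.json"
        write_pose_file(readiness_scene, path, render=100.0, image_height=800.0)
        raw = select_person(read_pose_file(path))
        kp = raw.keypoints.copy()
        kp[[L_HEEL, L_BIG_TOE], 1] -= 4.0  # front foot 0.04 m up: not "grounded"
        auto = calibrate(RawPose(kp), default_model)
        assert auto.support_state == "single_hind"
        forced = calibrate(
            RawPose(kp), default_model, CalibrationConfig(force_support="double")
        )
        assert forced.support_state == "double"

    def test_forced_double_rejects_airborne_foot(
        self, tmp_path, kick_scene, default_model
    ):
        path = tmp_path / "pose.json"
        write_pose_file(kick_scene, path)
        raw = select_person(read_pose_file(path))
        with pytest.raises(NoSupportError):
            calibrate(raw, default_model, CalibrationConfig(force_support="double"))

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(10.0, 1000.0), height=st.floats(0.0, 5000.0))
    def test_scale_invariance(self, scale, height, tmp_path_factory):
        model = generate(SceneParams(preset="readiness")).model
        scene = generate(SceneParams(preset="readiness"), model)
        path = tmp_path_factory.mktemp("poses") / "pose.json"
        write_pose_file(scene, path, render=scale, image_height=height)
        raw = select_person(read_pose_file(path))
        posture = calibrate(raw, model)
        np.testing.assert_allclose(
            posture.hind.knee, scene.posture.hind.knee, atol=1e-9 * scale
        )

    def test_mirror_invariance_of_leg_labels(
        self, tmp_path, readiness_scene, default_model
    ):
        path = tmp_path / "pose.json"
        write_pose_file(readiness_scene, path)
        raw = select_person(read_pose_file(path))
        posture = calibrate(raw, default_model)

        kp = raw.keypoints.copy()
        kp[:, 0] = -kp[:, 0]
        mirrored = calibrate(
            RawPose(kp), default_model, CalibrationConfig(facing_sign=-1)
        )
        # same physical legs keep their hind/front roles
        np.testing.assert_allclose(
            mirrored.hind.ankle[0], -posture.hind.ankle[0], atol=1e-9
        )
        np.testing.assert_allclose(
            mirrored.hind.ankle[1], posture.hind.ankle[1], atol=1e-9
        )
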