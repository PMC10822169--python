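"""Unit and property tests of the angle definitions, virtual-shoulder
construction and LOCF gap filling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointangles import (
    DegenerateGeometryError,
    Pose,
    TrajectorySet,
    UnrecoverableTrialError,
    alpha,
    beta,
    compute_angle_series,
    gamma,
    locf_fill,
    make_virtual_shoulder,
    simulate_truth,
    vector_angle,
)
from jointangles.angle_engine import JOINTS

from conftest import random_pose


def _oracle_angle(u, v):
    """Independent arccos oracle built from scalar math primitives only."""
    du = math.sqrt(sum(x * x for x in u))
    dv = math.sqrt(sum(x * x for x in v))
    dot = sum(a * b for a, b in zip(u, v))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (du * dv)))))


def _pose(time=0.0, **positions):
    base = {j: np.zeros(3) for j in JOINTS}
    base.update({k: np.asarray(v, float) for k, v in positions.items()})
    # spread unrelated joints so nothing coincides accidentally
    for i, j in enumerate(JOINTS):
        if j not in positions:
            base[j] = base[j] + np.array([0.0, 2.0 + 0.1 * i, 5.0])
    return Pose(time=time, positions=base, valid={j: True for j in JOINTS})


class TestVectorAngle:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((5, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (-3, 0, 0), 180.0),
            # frozen from the scalar-math oracle: acos(3/sqrt(294))
            ((1, 2, 3), (-2, 4, -1), 79.92346287144585),
        ],
    )
    def test_known_angles(self, u, v, expected):
        assert vector_angle(np.array(u, float), np.array(v, float)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            vector_angle(np.zeros(3), np.array([1.0, 0, 0]))

    @given(
        st.lists(st.floats(-10, 10), min_size=6, max_size=6),
        st.floats(0.1, 100.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetry_and_scale_invariance(self, coords, scale):
        u = np.array(coords[:3])
        v = np.array(coords[3:])
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        a = vector_angle(u, v)
        assert 0.0 <= a <= 180.0
        assert vector_angle(v, u) == pytest.approx(a, abs=1e-9)
        assert vector_angle(scale * u, v) == pytest.approx(a, abs=1e-9)


class TestVirtualShoulder:
    def test_coordinate_substitution(self):
        pose = _pose(left_shoulder=(0.2, 1.4, 2.0), chest=(0.0, 1.3, 2.05))
        np.testing.assert_allclose(
            make_virtual_shoulder(pose, "L"), [0.2, 1.3, 2.05]
        )

    def test_shoulder_coincides_with_chest(self):
        pose = _pose(left_shoulder=(0.1, 1.0, 2.0), chest=(0.1, 1.0, 2.0))
        np.testing.assert_allclose(make_virtual_shoulder(pose, "L"), [0.1, 1.0, 2.0])

    def test_missing_joint_signals_unresolvable(self):
        pose = _pose(left_shoulder=(0.2, 1.4, 2.0), chest=(0.0, 1.3, 2.05))
        pose.valid["chest"] = False
        with pytest.raises(DegenerateGeometryError):
            make_virtual_shoulder(pose, "L")

    def test_virtual_point_lies_in_chest_plane(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pose = random_pose(rng)
            for arm in ("L", "R"):
                v = make_virtual_shoulder(pose, arm)
                # shares the chest's height and depth, the shoulder's x
                assert v[1] == pose.positions["chest"][1]
                assert v[2] == pose.positions["chest"][2]
                side = "left" if arm == "L" else "right"
                assert v[0] == pose.positions[f"{side}_shoulder"][0]


class TestAngleDefinitions:
    def test_alpha_anchors(self):
        # elbow directly below the virtual shoulder: hanging arm
        pose = _pose(
            chest=(0.0, 1.3, 2.0),
            left_shoulder=(0.2, 1.3, 2.0),
            left_elbow=(0.2, 1.0, 2.0),
        )
        assert alpha(pose, "L") == pytest.approx(0.0, abs=1e-12)
        # elbow level with the virtual shoulder in the frontal plane
        pose = _pose(
            chest=(0.0, 1.3, 2.0),
            left_shoulder=(0.2, 1.3, 2.0),
            left_elbow=(0.5, 1.3, 2.0),
        )
        assert alpha(pose, "L") == pytest.approx(90.0, abs=1e-12)

    def test_alpha_inverse_construction(self):
        # place the elbow at 37 degrees from vertical in the frontal plane
        theta = math.radians(37.0)
        elbow = np.array([0.2 + 0.3 * math.sin(theta), 1.3 - 0.3 * math.cos(theta), 2.0])
        pose = _pose(
            chest=(0.0, 1.3, 2.0), left_shoulder=(0.2, 1.3, 2.0), left_elbow=elbow
        )
        assert alpha(pose, "L") == pytest.approx(37.0, abs=1e-9)

    def test_beta_collinear_and_right_angle(self):
        pose = _pose(
            left_shoulder=(0.2, 1.3, 2.0),
            left_elbow=(0.5, 1.3, 2.0),
            left_wrist=(0.8, 1.3, 2.0),
        )
        assert beta(pose, "L") == pytest.approx(180.0, abs=1e-12)
        pose = _pose(
            left_shoulder=(0.2, 1.3, 2.0),
            left_elbow=(0.5, 1.3, 2.0),
            left_wrist=(0.5, 1.0, 2.0),
        )
        assert beta(pose, "L") == pytest.approx(90.0, abs=1e-12)

    def test_beta_matches_oracle_on_arbitrary_triple(self):
        s, e, w = (0.1, 1.2, 2.1), (0.4, 1.0, 2.3), (0.6, 0.7, 1.9)
        pose = _pose(left_shoulder=s, left_elbow=e, left_wrist=w)
        expected = _oracle_angle(np.subtract(s, e), np.subtract(w, e))
        assert beta(pose, "L") == pytest.approx(expected, abs=1e-12)

    def test_gamma_anchors(self):
        # torso spanning x so the frontal normal is the depth axis
        common = dict(
            chest=(0.0, 1.3, 2.0),
            left_shoulder=(0.2, 1.3, 2.0),
            right_shoulder=(-0.2, 1.3, 2.0),
        )
        in_plane = _pose(left_elbow=(0.5, 1.1, 2.0), **common)
        assert gamma(in_plane, "L") == pytest.approx(90.0, abs=1e-12)
        at_camera = _pose(left_elbow=(0.2, 1.3, 1.5), **common)
        assert gamma(at_camera, "L") == pytest.approx(0.0, abs=1e-7)

    def test_gamma_out_of_plane_tilt_is_complementary(self):
        # arm tilted 20 degrees out of the frontal plane toward the camera
        tilt = math.radians(20.0)
        elbow = (
            0.2 + 0.3 * math.cos(tilt),
            1.3,
            2.0 - 0.3 * math.sin(tilt),
        )
        pose = _pose(
            chest=(0.0, 1.3, 2.0),
            left_shoulder=(0.2, 1.3, 2.0),
            right_shoulder=(-0.2, 1.3, 2.0),
            left_elbow=elbow,
        )
        assert gamma(pose, "L") == pytest.approx(70.0, abs=1e-9)

    def test_oracle_equivalence_on_random_poses(self):
        """alpha/beta/gamma agree with an independently coded arccos oracle
        to 1e-9 degrees on 10^4 random valid poses."""
        rng = np.random.default_rng(2024)
        down = (0.0, -1.0, 0.0)
        for _ in range(10_000):
            pose = random_pose(rng)
            arm = "L" if rng.random() < 0.5 else "R"
            side = "left" if arm == "L" else "right"
            s = pose.positions[f"{side}_shoulder"]
            e = pose.positions[f"{side}_elbow"]
            w = pose.positions[f"{side}_wrist"]
            c = pose.positions["chest"]
            vs = (s[0], c[1], c[2])
            arm_vec = tuple(e - vs)
            assert alpha(pose, arm) == pytest.approx(
                _oracle_angle(arm_vec, down), abs=1e-9
            )
            assert beta(pose, arm) == pytest.approx(
                _oracle_angle(tuple(s - e), tuple(w - e)), abs=1e-9
            )
            line = pose.positions["right_shoulder"] - pose.positions["left_shoulder"]
            normal = (-line[2], 0.0, line[0])  # cross(line, -y)
            assert gamma(pose, arm) == pytest.approx(
                _oracle_angle(arm_vec, normal), abs=1e-9
            )

    def test_reflection_symmetry(self):
        """Mirroring a pose in x swaps the arms: alpha_L of the mirror
        equals alpha_R of the original (same for beta, gamma)."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            pose = random_pose(rng)
            mirrored_positions = {}
            for j, p in pose.positions.items():
                if j.startswith("left"):
                    tgt = "right" + j[4:]
                elif j.startswith("right"):
                    tgt = "left" + j[5:]
                else:
                    tgt = j
                mirrored_positions[tgt] = p * np.array([-1.0, 1.0, 1.0])
            mirror = Pose(0.0, mirrored_positions, {j: True for j in JOINTS})
            assert alpha(mirror, "L") == pytest.approx(alpha(pose, "R"), abs=1e-9)
            assert beta(mirror, "L") == pytest.approx(beta(pose, "R"), abs=1e-9)
            assert gamma(mirror, "L") == pytest.approx(gamma(pose, "R"), abs=1e-9)


def _traj_with_validity(valid_elbow, n=20, fps=10.0):
    rng = np.random.default_rng(0)
    times = np.arange(n) / fps
    data = {j: rng.normal(size=(n, 3)) for j in JOINTS}
    valid = {j: np.ones(n, dtype=bool) for j in JOINTS}
    valid["left_elbow"] = np.asarray(valid_elbow, bool)
    data["left_elbow"][~valid["left_elbow"]] = np.nan
    return TrajectorySet(times, data, valid, fps=fps)


class TestLocf:
    def test_all_valid_is_noop(self):
        traj = _traj_with_validity(np.ones(20, bool))
        out = locf_fill(traj)
        assert out.n_frames == traj.n_frames
        for j in JOINTS:
            np.testing.assert_array_equal(out.data[j], traj.data[j])
        assert not out.filled.any()

    def test_gap_carries_last_valid_position(self):
        v = np.ones(20, bool)
        v[10:15] = False
        traj = _traj_with_validity(v)
        out = locf_fill(traj)
        for i in range(10, 15):
            np.testing.assert_array_equal(
                out.data["left_elbow"][i], traj.data["left_elbow"][9]
            )
            assert out.filled[i]
        np.testing.assert_array_equal(
            out.data["left_elbow"][15], traj.data["left_elbow"][15]
        )
        assert not out.filled[15]

    def test_leading_gap_drops_frames(self):
        v = np.ones(20, bool)
        v[:5] = False
        traj = _traj_with_validity(v)
        out = locf_fill(traj)
        assert out.n_frames == 15
        assert out.times[0] == traj.times[5]

    def test_never_valid_joint_is_unrecoverable(self):
        traj = _traj_with_validity(np.zeros(20, bool))
        with pytest.raises(UnrecoverableTrialError):
            locf_fill(traj)

    def test_idempotence(self):
        v = np.ones(20, bool)
        v[3:7] = False
        v[0] = False
        traj = _traj_with_validity(v)
        once = locf_fill(traj)
        twice = locf_fill(once)
        assert twice.n_frames == once.n_frames
        for j in JOINTS:
            np.testing.assert_array_equal(twice.data[j], once.data[j])


class TestAngleSeries:
    def test_noiseless_truth_hits_all_three_anchors(self, truth, sal_script):
        series = compute_angle_series(truth, "L")
        assert series.alpha.max() == pytest.approx(sal_script.peak_abduction, abs=1e-9)
        assert series.alpha.min() == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(series.beta, 180.0, atol=1e-5)
        np.testing.assert_allclose(series.gamma, 90.0, atol=1e-9)
        assert np.all(series.alpha >= 0) and np.all(series.alpha <= 180)

    def test_alpha_rises_and_returns_each_repetition(self, truth, sal_script):
        series = compute_angle_series(truth, "L")
        fps = truth.fps
        rest, rep = sal_script.rest_duration, sal_script.rep_duration
        for r in range(sal_script.n_reps):
            mid = rest + r * (rep + rest) + rep / 2
            i = int(round(mid * fps))
            assert series.alpha[i] == pytest.approx(90.0, abs=1e-6)
            end = int(round((rest + (r + 1) * rep + r * rest) * fps))
            assert series.alpha[end] == pytest.approx(0.0, abs=1e-6)

    def test_contralateral_arm_hangs(self, truth):
        series = compute_angle_series(truth, "R")
        np.testing.assert_allclose(series.alpha, 0.0, atol=1e-9)

    def test_frozen_elbow_produces_plateau(self, trial):
        truth = simulate_truth(trial)
        v = np.ones(truth.n_frames, bool)
        span = slice(400, 600)
        v[span] = False
        for j in ("left_elbow", "left_wrist"):
            truth.valid[j] = v.copy()
            truth.data[j][~v] = np.nan
        series = compute_angle_series(locf_fill(truth), "L")
        plateau = series.alpha[span]
        np.testing.assert_allclose(plateau, plateau[0], atol=1e-9)
        assert series.filled[span].all()

    def test_unfilled_trajectory_is_rejected(self, trial):
        truth = simulate_truth(trial)
        truth.valid["left_elbow"][100] = False
        with pytest.raises(DegenerateGeometryError, match="frame 100"):
            compute_angle_series(truth, "L")
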