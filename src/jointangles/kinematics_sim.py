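"""Forward-kinematic simulation of shoulder-abduction trials.

The validation study this package supports compared a marker-based optical
motion-capture reference against a depth-camera skeleton tracker, but the
participant recordings themselves are not available.  This module generates
a synthetic stand-in with the same statistical structure: a cohort of
subjects (the published demographic roster is packaged here), shoulder
abduction left/right at 5 repetitions, three camera distances, a 256 fps
low-noise marker stream with rigid anatomical marker offsets, and a 30 fps
noisier keypoint stream whose noise grows with distance and which drops the
elbow/wrist keypoints during fast motion.

Coordinate frame (camera-centered): x lateral (subject's left positive),
y vertical up with the camera at y = 0 (1 m above the ground), z depth
toward the subject.  The subject stands at (0, 0, distance) facing the
camera; the exercise is confined to the frontal plane z = distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .angle_engine import JOINTS, TrajectorySet

__all__ = [
    "SubjectModel",
    "ExerciseScript",
    "SensorProfile",
    "TrialConfig",
    "ANTHROPOMETRIC_RATIOS",
    "DEMOGRAPHICS",
    "reference_cohort",
    "mocap_profile",
    "sdk_profile",
    "abduction_profile",
    "simulate_truth",
    "observe_mocap",
    "observe_sdk",
]

#: Segment lengths as fixed fractions of standing height.  The chest marker
#: (suprasternal, above the sternum) sits at clavicle level, i.e. in the same
#: horizontal and frontal plane as the shoulder markers — this is what makes
#: the virtual-shoulder angle of a hanging arm exactly 0° and of a horizontal
#: arm exactly 90° on noiseless data.
ANTHROPOMETRIC_RATIOS: Dict[str, float] = {
    "upper_arm": 0.186,
    "forearm": 0.146,
    "shoulder_half_width": 0.129,
    "shoulder_height": 0.82,
    "chest_height": 0.82,
    "c7_height": 0.84,
    "ear_height": 0.93,
}

_CAMERA_HEIGHT = 1.0  # m above ground; ground plane is y = -1
_EAR_HALF_WIDTH = 0.07  # m
_C7_BACK_OFFSET = 0.07  # m behind the shoulder plane
_TRUTH_FPS = 256.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectModel:
    """Anthropometry of one participant.

    Segment lengths are derived deterministically from standing height via
    :data:`ANTHROPOMETRIC_RATIOS`; only the descriptors published in the
    demographic roster (sex, age, height, BMI) vary across the cohort.
    """

    subject_id: str
    sex: str
    age: float
    height: float
    bmi: float

    def __post_init__(self) -> None:
        if not (1.3 <= self.height <= 2.2):
            raise ValueError(f"height {self.height} m outside plausible range")

    @property
    def upper_arm_length(self) -> float:
        return ANTHROPOMETRIC_RATIOS["upper_arm"] * self.height

    @property
    def forearm_length(self) -> float:
        return ANTHROPOMETRIC_RATIOS["forearm"] * self.height

    @property
    def shoulder_half_width(self) -> float:
        return ANTHROPOMETRIC_RATIOS["shoulder_half_width"] * self.height

    @property
    def chest_height(self) -> float:
        return ANTHROPOMETRIC_RATIOS["chest_height"] * self.height


@dataclass(frozen=True)
class ExerciseScript:
    """One scripted exercise: repetitions of shoulder abduction.

    ``exercise`` is ``'SAL'`` (left arm) or ``'SAR'`` (right arm); each
    repetition sweeps the abduction angle 0 → ``peak_abduction`` → 0 with a
    raised-cosine velocity profile over ``rep_duration`` seconds, followed
    by ``rest_duration`` seconds at rest.
    """

    exercise: str = "SAL"
    n_reps: int = 5
    peak_abduction: float = 90.0
    rep_duration: float = 4.0
    rest_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.exercise not in ("SAL", "SAR"):
            raise ValueError(f"exercise must be SAL or SAR, got {self.exercise!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0.0 < self.peak_abduction <= 180.0):
            raise ValueError("peak_abduction must be in (0, 180]")
        if self.rep_duration <= 0 or self.rest_duration < 0:
            raise ValueError("durations must be positive (rest may be 0)")

    @property
    def arm(self) -> str:
        return "L" if self.exercise == "SAL" else "R"

    @property
    def duration(self) -> float:
        """Total trial length: leading rest, then reps separated by rests."""
        return self.rest_duration + self.n_reps * (
            self.rep_duration + self.rest_duration
        )

    @property
    def peak_speed(self) -> float:
        """Maximum angular speed of the raised-cosine profile, deg/s."""
        return self.peak_abduction * math.pi / self.rep_duration


@dataclass(frozen=True)
class SensorProfile:
    """Observation model of one measurement system.

    ``position_noise_sd_at_2m`` is the per-axis i.i.d. Gaussian keypoint
    noise at a 2 m camera distance; for the depth-camera tracker it scales
    as ``(distance / 2) ** noise_distance_exponent``.  ``marker_offsets``
    maps a joint to a rigid offset expressed in the local segment frame
    ``(longitudinal, posterior, lateral)`` in meters — only the
    marker-based system has them (e.g. the elbow marker glued on the back
    of the elbow).  Fast motion blurs the depth stream: frames where the
    exercising arm moves faster than ``dropout_speed_threshold`` deg/s lose
    the elbow and wrist keypoints with ``dropout_probability`` per frame.
    """

    system: str
    fps: float
    position_noise_sd_at_2m: float
    noise_distance_exponent: float = 0.0
    marker_offsets: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)
    dropout_speed_threshold: float = math.inf
    dropout_probability: float = 0.0
    latency_s: float = 0.0

    def __post_init__(self) -> None:
        if self.system not in ("mocap_like", "sdk_like"):
            raise ValueError(f"unknown system {self.system!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.position_noise_sd_at_2m < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0.0 <= self.dropout_probability <= 1.0):
            raise ValueError("dropout_probability must be in [0, 1]")
        if self.system == "sdk_like" and self.marker_offsets:
            raise ValueError("a marker-less tracker has no marker offsets")

    def noise_sd(self, distance: float) -> float:
        return self.position_noise_sd_at_2m * (distance / 2.0) ** (
            self.noise_distance_exponent
        )


def mocap_profile(
    noise_sd: float = 0.001,
    elbow_posterior_offset: float = 0.03,
) -> SensorProfile:
    """Default marker-based reference profile: 256 fps, low noise, and a
    posterior elbow-marker offset on both arms."""
    off = (0.0, elbow_posterior_offset, 0.0)
    return SensorProfile(
        system="mocap_like",
        fps=256.0,
        position_noise_sd_at_2m=noise_sd,
        noise_distance_exponent=0.0,
        marker_offsets={"left_elbow": off, "right_elbow": off},
    )


def sdk_profile(
    noise_sd_at_2m: float = 0.008,
    noise_distance_exponent: float = 1.5,
    dropout_speed_threshold: float = 45.0,
    dropout_probability: float = 0.3,
    latency_s: float = 0.0,
) -> SensorProfile:
    """Default depth-camera tracker profile: 30 fps, distance-dependent
    noise, velocity-gated elbow/wrist dropouts."""
    return SensorProfile(
        system="sdk_like",
        fps=30.0,
        position_noise_sd_at_2m=noise_sd_at_2m,
        noise_distance_exponent=noise_distance_exponent,
        dropout_speed_threshold=dropout_speed_threshold,
        dropout_probability=dropout_probability,
        latency_s=latency_s,
    )


@dataclass(frozen=True)
class TrialConfig:
    """One trial: subject × exercise script × camera distance × seed."""

    subject: SubjectModel
    script: ExerciseScript
    distance: float
    seed: int

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")


# ---------------------------------------------------------------------------
# Published demographic roster (14 participants)
# ---------------------------------------------------------------------------

#: (subject_id, sex, age [years], height [m], BMI [kg/m^2])
DEMOGRAPHICS: List[Tuple[str, str, int, float, float]] = [
    ("S1", "Female", 22, 1.59, 23.73),
    ("S2", "Female", 25, 1.68, 21.26),
    ("S3", "Male", 24, 1.75, 29.39),
    ("S4", "Female", 22, 1.62, 20.19),
    ("S5", "Female", 26, 1.68, 19.49),
    ("S6", "Male", 28, 1.80, 24.69),
    ("S7", "Male", 28, 1.92, 24.41),
    ("S8", "Male", 27, 1.75, 27.75),
    ("S9", "Female", 23, 1.65, 22.04),
    ("S10", "Male", 22, 1.75, 21.22),
    ("S11", "Female", 22, 1.75, 26.12),
    ("S12", "Male", 28, 1.70, 25.95),
    ("S13", "Female", 23, 1.60, 21.48),
    ("S14", "Female", 26, 1.65, 22.04),
]


def reference_cohort() -> List[SubjectModel]:
    """The 14-subject roster of the validation study as SubjectModels."""
    return [
        SubjectModel(subject_id=sid, sex=sex, age=age, height=h, bmi=bmi)
        for sid, sex, age, h, bmi in DEMOGRAPHICS
    ]


# ---------------------------------------------------------------------------
# Ground-truth kinematics
# ---------------------------------------------------------------------------


def abduction_profile(script: ExerciseScript, t: np.ndarray) -> np.ndarray:
    """True abduction angle (degrees) of the exercising arm at times ``t``.

    Raised-cosine per repetition: within a repetition of length ``T`` the
    angle is ``peak * (1 - cos(2*pi*tau/T)) / 2``, zero during rests.
    """
    t = np.asarray(t, dtype=float)
    phi = np.zeros_like(t)
    T = script.rep_duration
    for r in range(script.n_reps):
        start = script.rest_duration + r * (T + script.rest_duration)
        tau = t - start
        in_rep = (tau >= 0) & (tau <= T)
        phi = np.where(
            in_rep,
            script.peak_abduction * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / T)),
            phi,
        )
    return phi


def _skeleton(subject: SubjectModel, distance: float, phi_deg: np.ndarray, arm: str):
    """Joint positions (dict joint -> (n,3)) for abduction angles ``phi_deg``
    of arm ``arm``, the other arm hanging."""
    n = phi_deg.size
    h = subject.height
    y_sh = ANTHROPOMETRIC_RATIOS["shoulder_height"] * h - _CAMERA_HEIGHT
    y_ch = ANTHROPOMETRIC_RATIOS["chest_height"] * h - _CAMERA_HEIGHT
    y_c7 = ANTHROPOMETRIC_RATIOS["c7_height"] * h - _CAMERA_HEIGHT
    y_ear = ANTHROPOMETRIC_RATIOS["ear_height"] * h - _CAMERA_HEIGHT
    w = subject.shoulder_half_width
    ua, fa = subject.upper_arm_length, subject.forearm_length
    d = distance

    def const(x: float, y: float, z: float) -> np.ndarray:
        return np.broadcast_to(np.array([x, y, z]), (n, 3)).copy()

    data = {
        "chest": const(0.0, y_ch, d),
        "c7": const(0.0, y_c7, d + _C7_BACK_OFFSET),
        "left_ear": const(_EAR_HALF_WIDTH, y_ear, d),
        "right_ear": const(-_EAR_HALF_WIDTH, y_ear, d),
        "left_shoulder": const(w, y_sh, d),
        "right_shoulder": const(-w, y_sh, d),
    }

    phi = np.radians(phi_deg)
    for side, sign in (("left", 1.0), ("right", -1.0)):
        active = (arm == "L" and side == "left") or (arm == "R" and side == "right")
        ang = phi if active else np.zeros(n)
        # abduction raises the arm laterally outward in the frontal plane
        direction = np.column_stack(
            [sign * np.sin(ang), -np.cos(ang), np.zeros(n)]
        )
        shoulder = data[f"{side}_shoulder"]
        elbow = shoulder + ua * direction
        wrist = elbow + fa * direction  # elbow fully extended: collinear
        data[f"{side}_elbow"] = elbow
        data[f"{side}_wrist"] = wrist
    return data


def simulate_truth(config: TrialConfig) -> TrajectorySet:
    """Noiseless ground-truth trajectories for one trial at 256 fps.

    The exercising arm follows the script's raised-cosine abduction profile
    in the frontal plane with the elbow fully extended; the contralateral
    arm hangs at 0°.  All frames are valid.  Deterministic: depends only on
    ``config`` (the seed matters for the observers, not the truth).
    """
    script = config.script
    n = int(round(script.duration * _TRUTH_FPS)) + 1
    t = np.arange(n) / _TRUTH_FPS
    phi = abduction_profile(script, t)
    data = _skeleton(config.subject, config.distance, phi, script.arm)
    valid = {j: np.ones(n, dtype=bool) for j in data}
    meta = {
        "subject_id": config.subject.subject_id,
        "exercise": script.exercise,
        "distance": config.distance,
        "system": "truth",
    }
    return TrajectorySet(t, data, valid, fps=_TRUTH_FPS, meta=meta)


# ---------------------------------------------------------------------------
# Observers
# ---------------------------------------------------------------------------


def _resample_truth(truth: TrajectorySet, fps: float):
    """Linear-interpolate the truth onto a uniform grid at ``fps``."""
    t0, t1 = truth.times[0], truth.times[-1]
    n = int(math.floor((t1 - t0) * fps)) + 1
    t = t0 + np.arange(n) / fps
    data = {}
    for j, arr in truth.data.items():
        data[j] = np.column_stack(
            [np.interp(t, truth.times, arr[:, k]) for k in range(3)]
        )
    return t, data


def _segment_frame(shoulder: np.ndarray, elbow: np.ndarray) -> np.ndarray:
    """Per-frame orthonormal frame (n,3,3) of the upper arm: columns are
    longitudinal (shoulder→elbow), posterior, lateral axes."""
    l = elbow - shoulder
    l = l / np.linalg.norm(l, axis=1, keepdims=True)
    z = np.broadcast_to(np.array([0.0, 0.0, 1.0]), l.shape)
    # posterior = camera-away direction orthogonalised against the segment
    p = z - (np.sum(z * l, axis=1, keepdims=True)) * l
    norms = np.linalg.norm(p, axis=1, keepdims=True)
    # arm pointing straight down the depth axis: fall back to world-down
    fallback = np.broadcast_to(np.array([0.0, -1.0, 0.0]), l.shape)
    p = np.where(norms > 1e-9, p / np.maximum(norms, 1e-300), fallback)
    q = np.cross(l, p)
    return np.stack([l, p, q], axis=2)


def observe_mocap(
    truth: TrajectorySet, profile: SensorProfile, config: TrialConfig
) -> TrajectorySet:
    """Marker-based observation: resample to the profile's frame rate,
    displace each marker by its rigid anatomical offset (expressed in the
    local upper-arm frame, so it rotates with the segment) and add i.i.d.
    Gaussian noise.  All frames are valid."""
    if profile.system != "mocap_like":
        raise ValueError("observe_mocap requires a mocap_like profile")
    t, data = _resample_truth(truth, profile.fps)
    rng = np.random.default_rng([config.seed, 0xA0])

    for joint, off in profile.marker_offsets.items():
        side = "left" if joint.startswith("left") else "right"
        frame = _segment_frame(data[f"{side}_shoulder"], data[f"{side}_elbow"])
        offset_vec = frame @ np.asarray(off, dtype=float)
        data[joint] = data[joint] + offset_vec

    sd = profile.noise_sd(config.distance)
    if sd > 0:
        for j in data:
            data[j] = data[j] + rng.normal(0.0, sd, size=data[j].shape)

    n = t.size
    valid = {j: np.ones(n, dtype=bool) for j in data}
    meta = {**truth.meta, "system": "mocap"}
    return TrajectorySet(t, data, valid, fps=profile.fps, meta=meta)


def observe_sdk(
    truth: TrajectorySet, profile: SensorProfile, config: TrialConfig
) -> TrajectorySet:
    """Depth-camera tracker observation: resample to 30 fps, add Gaussian
    noise whose sd grows with camera distance, and invalidate the
    exercising arm's elbow and wrist (positions set to NaN) on fast-motion
    frames with the profile's dropout probability."""
    if profile.system != "sdk_like":
        raise ValueError("observe_sdk requires an sdk_like profile")
    t, data = _resample_truth(truth, profile.fps)
    rng = np.random.default_rng([config.seed, 0xB1])

    sd = profile.noise_sd(config.distance)
    if sd > 0:
        for j in data:
            data[j] = data[j] + rng.normal(0.0, sd, size=data[j].shape)

    n = t.size
    valid = {j: np.ones(n, dtype=bool) for j in data}

    script = config.script
    speed = np.abs(
        np.gradient(abduction_profile(script, t), t) if n > 1 else np.zeros(n)
    )
    fast = speed > profile.dropout_speed_threshold
    drop = fast & (rng.random(n) < profile.dropout_probability)
    side = "left" if script.arm == "L" else "right"
    for j in (f"{side}_elbow", f"{side}_wrist"):
        valid[j] = ~drop
        data[j][drop] = np.nan

    if profile.latency_s:
        t = t + profile.latency_s

    meta = {**truth.meta, "system": "sdk"}
    return TrajectorySet(t, data, valid, fps=profile.fps, meta=meta)
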