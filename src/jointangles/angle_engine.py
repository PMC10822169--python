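"""Three-dimensional joint angles from skeletal keypoints.

Computes the three angles used to assess a shoulder-abduction repetition:

* ``alpha`` — shoulder abduction: angle between the upper-arm vector and the
  body-down direction (0° arm hanging, 90° arm horizontal).
* ``beta`` — elbow extension: angle at the elbow between upper arm and
  forearm (180° fully extended).
* ``gamma`` — arm–body angle in the transverse plane: angle between the arm
  vector and the normal to the participant's frontal plane (90° when the arm
  stays in the frontal plane, i.e. no motion toward/away from the camera).

The shoulder angle is measured from a *virtual* shoulder joint that shares
the physical shoulder's lateral coordinate but the chest marker's height and
depth, so a marker-based reference system and a depth-camera skeleton
tracker measure the same quantity despite different physical landmark
placement.

Frames where the tracker failed to detect a joint are repaired by carrying
the last valid observation forward (:func:`locf_fill`) before any angle is
computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "JOINTS",
    "ARM_JOINTS",
    "Pose",
    "TrajectorySet",
    "AngleSample",
    "AngleSeries",
    "DegenerateGeometryError",
    "UnrecoverableTrialError",
    "vector_angle",
    "make_virtual_shoulder",
    "alpha",
    "beta",
    "gamma",
    "locf_fill",
    "compute_angle_series",
]

#: Tracked joint names (upper-extremity marker set: head, trunk and both arms).
JOINTS: Tuple[str, ...] = (
    "chest",
    "c7",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
)

#: Joints contributing to the angles of one arm, keyed by arm side.
ARM_JOINTS: Dict[str, Tuple[str, ...]] = {
    "L": ("chest", "left_shoulder", "left_elbow", "left_wrist"),
    "R": ("chest", "right_shoulder", "right_elbow", "right_wrist"),
}

_DOWN = np.array([0.0, -1.0, 0.0])
# anterior-pointing frontal-plane normal of a camera-facing subject: out of
# the subject's front, toward the camera (depth axis points at the subject)
_CAMERA_NORMAL = np.array([0.0, 0.0, -1.0])


class DegenerateGeometryError(ValueError):
    """A zero-length segment or collapsed torso makes an angle undefined."""


class UnrecoverableTrialError(ValueError):
    """A required joint was never detected in the whole trial."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class Pose:
    """One time-stamped set of named 3D joint positions with validity flags.

    Positions are in meters, camera-centered coordinates: x lateral
    (subject's left positive), y vertical up, z depth toward the subject.
    """

    time: float
    positions: Dict[str, np.ndarray]
    valid: Dict[str, bool]

    def __post_init__(self) -> None:
        for name in self.positions:
            if name not in self.valid:
                raise ValueError(f"joint {name!r} has no validity flag")
            self.positions[name] = np.asarray(self.positions[name], dtype=float)
            if self.valid[name] and not np.all(np.isfinite(self.positions[name])):
                raise ValueError(f"joint {name!r} flagged valid but not finite")


@dataclass
class TrajectorySet:
    """A fixed-rate sequence of poses for one trial.

    Stored densely: ``times`` is shape ``(n,)``, ``data[joint]`` is
    ``(n, 3)`` and ``valid[joint]`` is ``(n,)`` boolean.  ``meta`` carries
    ``(subject_id, exercise, distance, system)`` provenance.
    """

    times: np.ndarray
    data: Dict[str, np.ndarray]
    valid: Dict[str, np.ndarray]
    fps: float
    meta: Dict[str, object] = field(default_factory=dict)
    filled: Optional[np.ndarray] = None  # per-frame: any joint LOCF-substituted

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.size
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fps, rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing inconsistent with fps")
        for j, arr in self.data.items():
            self.data[j] = np.asarray(arr, dtype=float).reshape(n, 3)
            self.valid[j] = np.asarray(self.valid[j], dtype=bool).reshape(n)
        if self.filled is None:
            self.filled = np.zeros(n, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def joints(self) -> List[str]:
        return list(self.data)

    def pose(self, i: int) -> Pose:
        """Materialise frame ``i`` as a :class:`Pose`."""
        return Pose(
            time=float(self.times[i]),
            positions={j: self.data[j][i].copy() for j in self.data},
            valid={j: bool(self.valid[j][i]) for j in self.data},
        )

    @classmethod
    def from_poses(
        cls,
        poses: Sequence[Pose],
        fps: float,
        meta: Optional[Mapping[str, object]] = None,
    ) -> "TrajectorySet":
        if not poses:
            raise ValueError("empty pose sequence")
        joints = list(poses[0].positions)
        times = np.array([p.time for p in poses])
        data = {
            j: np.stack([np.where(p.valid[j], p.positions[j], np.nan) for p in poses])
            for j in joints
        }
        valid = {j: np.array([p.valid[j] for p in poses]) for j in joints}
        return cls(times, data, valid, fps=fps, meta=dict(meta or {}))


@dataclass
class AngleSample:
    """Per-frame (alpha, beta, gamma) for one arm, degrees."""

    time: float
    alpha: float
    beta: float
    gamma: float
    arm: str
    filled: bool = False


@dataclass
class AngleSeries:
    """Angle traces for one arm of one trial, on the source frame grid."""

    times: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    arm: str
    fps: float
    filled: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("alpha", "beta", "gamma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.filled = np.asarray(self.filled, dtype=bool)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def samples(self) -> List[AngleSample]:
        return [
            AngleSample(
                time=float(self.times[i]),
                alpha=float(self.alpha[i]),
                beta=float(self.beta[i]),
                gamma=float(self.gamma[i]),
                arm=self.arm,
                filled=bool(self.filled[i]),
            )
            for i in range(len(self))
        ]

    def angle(self, name: str) -> np.ndarray:
        if name not in ("alpha", "beta", "gamma"):
            raise KeyError(name)
        return getattr(self, name)


# ---------------------------------------------------------------------------
# Primitive
# ---------------------------------------------------------------------------


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two 3D vectors in degrees, in [0, 180].

    The normalized dot product is clamped to [-1, 1] to absorb rounding.
    Raises :class:`DegenerateGeometryError` on a zero-length vector.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length vector has no direction")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _vector_angle_array(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorised :func:`vector_angle` over ``(n, 3)`` stacks."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0.0) or np.any(nv == 0.0):
        bad = int(np.argmax((nu == 0.0) | (nv == 0.0)))
        raise DegenerateGeometryError(f"zero-length vector at frame {bad}")
    c = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Per-pose angle definitions
# ---------------------------------------------------------------------------


def _arm_prefix(arm: str) -> str:
    if arm not in ("L", "R"):
        raise ValueError(f"arm must be 'L' or 'R', got {arm!r}")
    return "left" if arm == "L" else "right"


def make_virtual_shoulder(pose: Pose, arm: str) -> np.ndarray:
    """Virtual shoulder joint: physical shoulder's lateral (x) coordinate,
    chest marker's height (y) and depth (z).

    Requires both the physical shoulder of ``arm`` and the chest joint to be
    valid; the caller is expected to have gap-filled the pose first.
    """
    side = _arm_prefix(arm)
    shoulder = f"{side}_shoulder"
    if not pose.valid.get(shoulder, False) or not pose.valid.get("chest", False):
        raise DegenerateGeometryError(
            f"virtual shoulder needs valid {shoulder} and chest"
        )
    s = pose.positions[shoulder]
    c = pose.positions["chest"]
    return np.array([s[0], c[1], c[2]])


def _frontal_normal(pose: Pose) -> np.ndarray:
    """Unit normal to the participant's frontal plane.

    Estimated per frame as the anterior-pointing cross product of the world
    down vector with the shoulder line (right − left); falls back to the
    toward-camera depth direction when either shoulder is invalid
    (reasonable for a camera-facing subject).
    """
    if pose.valid.get("left_shoulder", False) and pose.valid.get(
        "right_shoulder", False
    ):
        line = pose.positions["right_shoulder"] - pose.positions["left_shoulder"]
        n = np.cross(_DOWN, line)
        norm = np.linalg.norm(n)
        if norm > 1e-12:
            return n / norm
        raise DegenerateGeometryError("collapsed shoulder line, frontal normal undefined")
    return _CAMERA_NORMAL.copy()


def _arm_vector(pose: Pose, arm: str, endpoint: str = "elbow") -> np.ndarray:
    side = _arm_prefix(arm)
    joint = f"{side}_{endpoint}"
    if not pose.valid.get(joint, False):
        raise DegenerateGeometryError(f"{joint} invalid; gap-fill first")
    return pose.positions[joint] - make_virtual_shoulder(pose, arm)


def alpha(pose: Pose, arm: str, endpoint: str = "elbow") -> float:
    """Shoulder abduction angle in degrees (0° hanging, 90° horizontal).

    Angle between the arm vector (virtual shoulder → elbow, or wrist when
    ``endpoint='wrist'``) and the body-down direction.
    """
    return vector_angle(_arm_vector(pose, arm, endpoint), _DOWN)


def beta(pose: Pose, arm: str) -> float:
    """Elbow angle in degrees: angle at the elbow between the vectors to the
    physical shoulder and to the wrist (180° fully extended)."""
    side = _arm_prefix(arm)
    for j in (f"{side}_shoulder", f"{side}_elbow", f"{side}_wrist"):
        if not pose.valid.get(j, False):
            raise DegenerateGeometryError(f"{j} invalid; gap-fill first")
    e = pose.positions[f"{side}_elbow"]
    return vector_angle(
        pose.positions[f"{side}_shoulder"] - e,
        pose.positions[f"{side}_wrist"] - e,
    )


def gamma(pose: Pose, arm: str) -> float:
    """Arm–body transverse angle in degrees: angle between the arm vector
    and the frontal-plane normal (90° for a frontal-plane arm)."""
    return vector_angle(_arm_vector(pose, arm), _frontal_normal(pose))


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------


def locf_fill(
    traj: TrajectorySet, required_joints: Optional[Iterable[str]] = None
) -> TrajectorySet:
    """Last-observation-carried-forward repair of missing joints.

    Every invalid sample of a required joint is replaced by that joint's
    most recent valid position.  Frames preceding a required joint's first
    valid detection are dropped.  The returned trajectory records, per
    frame, whether any required joint was substituted (``filled``).

    Raises :class:`UnrecoverableTrialError` if a required joint is never
    valid in the whole trial.
    """
    required = list(required_joints) if required_joints is not None else traj.joints
    n = traj.n_frames
    start = 0
    for j in required:
        if j not in traj.valid:
            raise KeyError(f"unknown joint {j!r}")
        v = traj.valid[j]
        if not v.any():
            raise UnrecoverableTrialError(
                f"joint {j!r} never detected in trial {traj.meta or ''}"
            )
        start = max(start, int(np.argmax(v)))

    sl = slice(start, n)
    data = {j: traj.data[j][sl].copy() for j in traj.data}
    valid = {j: traj.valid[j][sl].copy() for j in traj.valid}
    filled = np.zeros(n - start, dtype=bool)

    for j in required:
        v = valid[j]
        if v.all():
            continue
        # index of the most recent valid frame, per frame
        idx = np.where(v, np.arange(v.size), -1)
        idx = np.maximum.accumulate(idx)
        data[j] = data[j][idx]
        filled |= ~v
        valid[j] = np.ones_like(v)

    return TrajectorySet(
        traj.times[sl].copy(),
        data,
        valid,
        fps=traj.fps,
        meta=dict(traj.meta),
        filled=filled,
    )


# ---------------------------------------------------------------------------
# Series computation (vectorised; per-pose functions define the semantics)
# ---------------------------------------------------------------------------


def compute_angle_series(
    traj: TrajectorySet, arm: str, alpha_endpoint: str = "elbow"
) -> AngleSeries:
    """Compute per-frame (alpha, beta, gamma) for one arm of a gap-filled
    trajectory.

    Input must have all arm joints valid on every frame (run
    :func:`locf_fill` first); a frame with an invalid required joint raises
    :class:`DegenerateGeometryError` naming the frame.
    """
    side = _arm_prefix(arm)
    required = ARM_JOINTS[arm]
    for j in required:
        if not traj.valid[j].all():
            bad = int(np.argmax(~traj.valid[j]))
            raise DegenerateGeometryError(
                f"{j} invalid at frame {bad}; apply locf_fill first"
            )

    chest = traj.data["chest"]
    shoulder = traj.data[f"{side}_shoulder"]
    elbow = traj.data[f"{side}_elbow"]
    wrist = traj.data[f"{side}_wrist"]

    vshoulder = np.column_stack([shoulder[:, 0], chest[:, 1], chest[:, 2]])
    endpoint = {"elbow": elbow, "wrist": wrist}[alpha_endpoint]
    arm_vec = endpoint - vshoulder

    n = traj.n_frames
    down = np.broadcast_to(_DOWN, (n, 3))
    a = _vector_angle_array(arm_vec, down)
    b = _vector_angle_array(shoulder - elbow, wrist - elbow)

    if traj.valid["left_shoulder"].all() and traj.valid["right_shoulder"].all():
        line = traj.data["right_shoulder"] - traj.data["left_shoulder"]
        normal = np.cross(np.broadcast_to(_DOWN, line.shape), line)
        norms = np.linalg.norm(normal, axis=1, keepdims=True)
        if np.any(norms <= 1e-12):
            bad = int(np.argmax(norms[:, 0] <= 1e-12))
            raise DegenerateGeometryError(
                f"collapsed shoulder line at frame {bad}, frontal normal undefined"
            )
        normal = normal / norms
    else:
        normal = np.broadcast_to(_CAMERA_NORMAL, (n, 3))
    g = _vector_angle_array(elbow - vshoulder, normal)

    return AngleSeries(
        times=traj.times.copy(),
        alpha=a,
        beta=b,
        gamma=g,
        arm=arm,
        fps=traj.fps,
        filled=(traj.filled.copy() if traj.filled is not None else np.zeros(n, bool)),
        meta=dict(traj.meta),
    )
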