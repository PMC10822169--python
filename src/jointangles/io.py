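"""Trajectory file format and run configuration.

Trajectories travel as long-format CSV — one joint observation per row
with columns ``time_s, joint, x_m, y_m, z_m, valid`` — preceded by a
sidecar header of commented ``# key=value`` lines carrying trial metadata
(subject, exercise, distance, system, fps).  The format is plain text on
purpose: no binary motion-capture dependency, and the column semantics
make a TRC importer trivial to add later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .angle_engine import AngleSeries, TrajectorySet

__all__ = [
    "COLUMNS",
    "read_trajectory",
    "write_trajectory",
    "write_angle_series",
    "read_angle_series",
    "RunConfig",
    "load_run_config",
]

COLUMNS = ("time_s", "joint", "x_m", "y_m", "z_m", "valid")

_META_KEYS = ("subject_id", "exercise", "distance", "system", "fps", "rep_duration")
_FLOAT_META = ("distance", "fps", "rep_duration")


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message carries the offending line."""


def write_trajectory(traj: TrajectorySet, path: str | Path) -> None:
    """Write a trajectory as long-format CSV with a commented metadata
    header.  Invalid samples are stored with empty coordinates."""
    path = Path(path)
    meta = {**traj.meta, "fps": traj.fps}
    with open(path, "w") as fh:
        for k in _META_KEYS:
            if k in meta and meta[k] is not None:
                fh.write(f"# {k}={meta[k]}\n")
        fh.write(",".join(COLUMNS) + "\n")
        for i in range(traj.n_frames):
            t = traj.times[i]
            for j in traj.data:
                ok = bool(traj.valid[j][i])
                if ok:
                    x, y, z = traj.data[j][i]
                    fh.write(f"{t:.9f},{j},{x:.9f},{y:.9f},{z:.9f},1\n")
                else:
                    fh.write(f"{t:.9f},{j},,,,0\n")


def read_trajectory(path: str | Path) -> TrajectorySet:
    """Parse a trajectory CSV written by :func:`write_trajectory`.

    Rows may appear in any order within a timestamp.  Malformed headers,
    non-monotone time or inconsistent joint sets raise
    :class:`TrajectoryParseError` with the line number.
    """
    path = Path(path)
    meta: Dict[str, object] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" not in body:
                raise TrajectoryParseError(
                    f"{path}:{header_lines}: malformed header line {line.strip()!r}"
                )
            k, v = body.split("=", 1)
            k = k.strip()
            meta[k] = float(v) if k in _FLOAT_META else v.strip()
        else:
            raise TrajectoryParseError(f"{path}: no data after header")
        if line.strip() != ",".join(COLUMNS):
            raise TrajectoryParseError(
                f"{path}:{header_lines + 1}: expected header {','.join(COLUMNS)!r}, "
                f"got {line.strip()!r}"
            )

    try:
        df = pd.read_csv(
            path,
            skiprows=header_lines,
            dtype={"joint": str},
        )
    except Exception as exc:  # malformed body
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    if list(df.columns) != list(COLUMNS):
        raise TrajectoryParseError(f"{path}: unexpected columns {list(df.columns)}")
    if df["valid"].isna().any() or not df["valid"].isin([0, 1]).all():
        raise TrajectoryParseError(f"{path}: valid column must be 0/1")
    if (df.loc[df["valid"] == 1, ["x_m", "y_m", "z_m"]].isna().any(axis=None)):
        raise TrajectoryParseError(f"{path}: valid rows with missing coordinates")

    fps = float(meta.pop("fps", 0) or 0)
    if fps <= 0:
        raise TrajectoryParseError(f"{path}: missing or invalid fps header")

    times = np.array(sorted(df["time_s"].unique()))
    joints = list(dict.fromkeys(df["joint"]))
    n = times.size
    counts = df.groupby("time_s").size()
    if counts.nunique() != 1 or int(counts.iloc[0]) != len(joints):
        raise TrajectoryParseError(
            f"{path}: truncated or ragged file — every frame must list every joint"
        )

    t_index = {t: i for i, t in enumerate(times)}
    data = {j: np.full((n, 3), np.nan) for j in joints}
    valid = {j: np.zeros(n, dtype=bool) for j in joints}
    for row in df.itertuples(index=False):
        i = t_index[row.time_s]
        if row.valid == 1:
            data[row.joint][i] = (row.x_m, row.y_m, row.z_m)
            valid[row.joint][i] = True
    try:
        return TrajectorySet(times, data, valid, fps=fps, meta=meta)
    except ValueError as exc:
        raise TrajectoryParseError(f"{path}: {exc}") from exc


def write_angle_series(series: AngleSeries, path: str | Path) -> None:
    path = Path(path)
    meta = {**series.meta, "fps": series.fps, "arm": series.arm}
    with open(path, "w") as fh:
        for k, v in meta.items():
            if np.isscalar(v) or isinstance(v, str):
                fh.write(f"# {k}={v}\n")
        fh.write("time_s,alpha_deg,beta_deg,gamma_deg,filled\n")
        for i in range(len(series)):
            fh.write(
                f"{series.times[i]:.9f},{series.alpha[i]:.9f},"
                f"{series.beta[i]:.9f},{series.gamma[i]:.9f},"
                f"{int(series.filled[i])}\n"
            )


def read_angle_series(path: str | Path) -> AngleSeries:
    path = Path(path)
    meta: Dict[str, object] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            k, v = line[1:].strip().split("=", 1)
            k = k.strip()
            meta[k] = float(v) if k in _FLOAT_META else v.strip()
    df = pd.read_csv(path, skiprows=header_lines)
    fps = float(meta.pop("fps"))
    arm = str(meta.pop("arm"))
    return AngleSeries(
        times=df["time_s"].to_numpy(),
        alpha=df["alpha_deg"].to_numpy(),
        beta=df["beta_deg"].to_numpy(),
        gamma=df["gamma_deg"].to_numpy(),
        arm=arm,
        fps=fps,
        filled=df["filled"].to_numpy().astype(bool),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ALLOWED_KEYS = {
    "subjects",
    "distances",
    "exercises",
    "n_reps",
    "peak_abduction",
    "rest_duration",
    "seed",
    "comparison_fps",
    "max_lag_s",
    "r2_variant",
    "sdk_noise_sd_at_2m",
    "sdk_noise_distance_exponent",
    "sdk_dropout_speed_threshold",
    "sdk_dropout_probability",
    "mocap_noise_sd",
    "mocap_elbow_posterior_offset",
    "train_frac",
    "calibration_families",
}


@dataclass
class RunConfig:
    """Validated configuration of a full simulate → report run.

    ``subjects='table5'`` selects the packaged 14-subject roster; a list
    of subject ids selects a sub-cohort of it.
    """

    subjects: object = "table5"
    distances: Sequence[float] = (2.0, 2.5, 3.5)
    exercises: Sequence[str] = ("SAL", "SAR")
    n_reps: int = 5
    peak_abduction: float = 90.0
    rest_duration: float = 1.0
    seed: int = 0
    comparison_fps: float = 30.0
    max_lag_s: float = 2.0
    r2_variant: str = "correlation"
    sdk_noise_sd_at_2m: float = 0.008
    sdk_noise_distance_exponent: float = 1.5
    sdk_dropout_speed_threshold: float = 45.0
    sdk_dropout_probability: float = 0.3
    mocap_noise_sd: float = 0.001
    mocap_elbow_posterior_offset: float = 0.03
    train_frac: float = 0.8
    calibration_families: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.distances):
            raise ValueError("distances must be positive")
        if any(e not in ("SAL", "SAR") for e in self.exercises):
            raise ValueError("exercises must be SAL/SAR")
        if self.r2_variant not in ("correlation", "identity"):
            raise ValueError("r2_variant must be 'correlation' or 'identity'")

    def to_dict(self) -> Dict[str, object]:
        return {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in self.__dict__.items()
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are
    rejected rather than silently ignored."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
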