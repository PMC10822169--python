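"""End-to-end plumbing: simulate a cohort, compute angles, align, score.

These helpers chain the public modules exactly the way the command-line
subcommands do, so programmatic runs and shell runs share one code path.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import calibration as cal
from . import evaluation as ev
from .angle_engine import (
    ARM_JOINTS,
    AngleSeries,
    TrajectorySet,
    compute_angle_series,
    locf_fill,
)
from .io import RunConfig
from .kinematics_sim import (
    ExerciseScript,
    SensorProfile,
    SubjectModel,
    TrialConfig,
    mocap_profile,
    observe_mocap,
    observe_sdk,
    reference_cohort,
    sdk_profile,
    simulate_truth,
)
from .signal_prep import AlignedPair, resample, synchronize

__all__ = [
    "trial_configs",
    "simulate_trial_pair",
    "trial_angle_series",
    "trial_aligned_pairs",
    "run_agreement_analysis",
    "calibration_datasets",
]

#: joints that must be present to compute one arm's three angles
def required_joints(arm: str) -> Tuple[str, ...]:
    side = "left" if arm == "L" else "right"
    return ("chest", "left_shoulder", "right_shoulder", f"{side}_elbow", f"{side}_wrist")


def _cohort(cfg: RunConfig) -> List[SubjectModel]:
    roster = reference_cohort()
    if cfg.subjects == "table5":
        return roster
    wanted = set(cfg.subjects)
    chosen = [s for s in roster if s.subject_id in wanted]
    missing = wanted - {s.subject_id for s in chosen}
    if missing:
        raise ValueError(f"unknown subject ids {sorted(missing)}")
    return chosen


def _rep_duration(subject: SubjectModel) -> float:
    """Per-subject repetition speed: subjects differ in how fast they sweep
    the arm; spread deterministically around 4 s per repetition."""
    h = sum(ord(c) for c in subject.subject_id)
    return 3.2 + 0.4 * (h % 5)


def trial_configs(cfg: RunConfig) -> List[TrialConfig]:
    """The full trial grid (subject × exercise × distance) of a run."""
    out = []
    for subject in _cohort(cfg):
        for exercise in cfg.exercises:
            script = ExerciseScript(
                exercise=exercise,
                n_reps=cfg.n_reps,
                peak_abduction=cfg.peak_abduction,
                rep_duration=_rep_duration(subject),
                rest_duration=cfg.rest_duration,
            )
            for distance in cfg.distances:
                seed = cal.stratum_seed(
                    cfg.seed, f"{subject.subject_id}|{exercise}|{distance}"
                )
                out.append(TrialConfig(subject, script, float(distance), seed))
    return out


def _profiles(cfg: RunConfig) -> Tuple[SensorProfile, SensorProfile]:
    return (
        mocap_profile(
            noise_sd=cfg.mocap_noise_sd,
            elbow_posterior_offset=cfg.mocap_elbow_posterior_offset,
        ),
        sdk_profile(
            noise_sd_at_2m=cfg.sdk_noise_sd_at_2m,
            noise_distance_exponent=cfg.sdk_noise_distance_exponent,
            dropout_speed_threshold=cfg.sdk_dropout_speed_threshold,
            dropout_probability=cfg.sdk_dropout_probability,
        ),
    )


def simulate_trial_pair(
    trial: TrialConfig, cfg: Optional[RunConfig] = None
) -> Tuple[TrajectorySet, TrajectorySet]:
    """Simulate one trial and observe it with both systems.

    Returns ``(mocap_like, sdk_like)`` trajectories; both carry
    ``rep_duration`` in their metadata for downstream alignment guards.
    """
    cfg = cfg or RunConfig()
    mp, sp = _profiles(cfg)
    truth = simulate_truth(trial)
    mocap = observe_mocap(truth, mp, trial)
    sdk = observe_sdk(truth, sp, trial)
    for tr in (mocap, sdk):
        tr.meta["rep_duration"] = trial.script.rep_duration
    return mocap, sdk


def trial_angle_series(
    traj: TrajectorySet, arm: str
) -> AngleSeries:
    """Gap-fill a trajectory and compute the exercising arm's angles."""
    filled = locf_fill(traj, required_joints(arm))
    return compute_angle_series(filled, arm)


def trial_aligned_pairs(
    mocap: TrajectorySet,
    sdk: TrajectorySet,
    arm: str,
    comparison_fps: float = 30.0,
    max_lag: float = 2.0,
) -> Dict[str, AlignedPair]:
    """Angles from both streams, resampled to the comparison rate and
    synchronized; reference = mocap-like, test = sdk-like."""
    ref = resample(trial_angle_series(mocap, arm), comparison_fps)
    test = resample(trial_angle_series(sdk, arm), comparison_fps)
    return synchronize(ref, test, max_lag=max_lag)


def run_agreement_analysis(cfg: RunConfig) -> Dict[str, object]:
    """Simulate the whole cohort and compute the agreement battery.

    Returns a dict with:

    * ``reports`` — list of per-trial per-angle :class:`MetricReport`;
    * ``table`` — mean ± sd aggregate across subjects (angle × arm ×
      distance);
    * ``distance_test`` — Friedman + post-hoc over the three distances on
      per-subject shoulder-angle MAE (SAL and SAR pooled as separate
      matched units);
    * ``arm_test`` — Wilcoxon between matched left/right shoulder-angle
      samples (per subject × distance mean shoulder angle);
    * ``normality`` — Shapiro–Wilk and KS on the pooled shoulder-angle
      errors;
    * ``pairs`` — the aligned pairs, keyed by (subject, exercise,
      distance, angle).
    """
    reports: List[ev.MetricReport] = []
    pairs_by_key: Dict[Tuple[str, str, float, str], AlignedPair] = {}
    mae_rows: List[Dict[str, object]] = []
    arm_mean_rows: List[Dict[str, object]] = []

    for trial in trial_configs(cfg):
        mocap, sdk = simulate_trial_pair(trial, cfg)
        arm = trial.script.arm
        pairs = trial_aligned_pairs(
            mocap, sdk, arm, comparison_fps=cfg.comparison_fps, max_lag=cfg.max_lag_s
        )
        sid = trial.subject.subject_id
        exercise = trial.script.exercise
        for angle_name, pair in pairs.items():
            pair.meta.update(
                subject_id=sid, exercise=exercise, distance=trial.distance
            )
            pairs_by_key[(sid, exercise, trial.distance, angle_name)] = pair
            rep = ev.agreement_metrics(pair, r2_variant=cfg.r2_variant)
            rep.meta = {
                "angle": angle_name,
                "arm": arm,
                "subject_id": sid,
                "exercise": exercise,
                "distance": trial.distance,
            }
            reports.append(rep)
            if angle_name == "alpha":
                mae_rows.append(
                    {
                        "unit": f"{sid}|{exercise}",
                        "distance": trial.distance,
                        "mae": rep.mae,
                    }
                )
                arm_mean_rows.append(
                    {
                        "subject_id": sid,
                        "distance": trial.distance,
                        "arm": arm,
                        "mean_alpha": float(np.mean(pair.test)),
                    }
                )

    table = ev.aggregate_report(reports, grouping=("angle", "arm", "distance"))

    mae_df = pd.DataFrame(mae_rows)
    by_distance = {
        d: g.sort_values("unit")["mae"].to_numpy()
        for d, g in mae_df.groupby("distance")
    }
    distance_test = (
        ev.distance_effect_test(by_distance) if len(by_distance) >= 3 else None
    )

    arm_df = pd.DataFrame(arm_mean_rows)
    arm_test = None
    if set(arm_df["arm"]) == {"L", "R"}:
        wide = arm_df.pivot_table(
            index=["subject_id", "distance"], columns="arm", values="mean_alpha"
        ).dropna()
        if len(wide) >= 3:
            arm_test = ev.arm_difference_test(
                wide["L"].to_numpy(), wide["R"].to_numpy()
            )

    errors = np.concatenate(
        [
            p.test - p.reference
            for (_, _, _, a), p in pairs_by_key.items()
            if a == "alpha"
        ]
    )
    normality = ev.normality_tests(errors)

    return {
        "reports": reports,
        "table": table,
        "distance_test": distance_test,
        "arm_test": arm_test,
        "normality": normality,
        "pairs": pairs_by_key,
    }


def calibration_datasets(
    pairs_by_key: Dict[Tuple[str, str, float, str], AlignedPair]
) -> List[cal.CalibrationDataset]:
    """Shoulder-angle calibration strata (one per subject × exercise ×
    distance) from aligned pairs."""
    out = []
    for (sid, exercise, distance, angle_name), pair in sorted(pairs_by_key.items()):
        if angle_name != "alpha":
            continue
        out.append(
            cal.CalibrationDataset(
                x=pair.test,
                y=pair.reference,
                meta={
                    "subject_id": sid,
                    "exercise": exercise,
                    "distance": distance,
                    "arm": pair.arm,
                },
            )
        )
    return out
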