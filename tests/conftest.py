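import numpy as np
import pytest

from jointangles import (
    ExerciseScript,
    SubjectModel,
    TrialConfig,
    simulate_truth,
)
from jointangles.angle_engine import JOINTS, Pose


@pytest.fixture
def subject():
    return SubjectModel(subject_id="S1", sex="Female", age=22, height=1.59, bmi=23.73)


@pytest.fixture
def sal_script():
    return ExerciseScript(exercise="SAL", n_reps=2, rep_duration=4.0, rest_duration=1.0)


@pytest.fixture
def trial(subject, sal_script):
    return TrialConfig(subject=subject, script=sal_script, distance=2.0, seed=123)


@pytest.fixture
def truth(trial):
    return simulate_truth(trial)


def random_pose(rng: np.random.Generator) -> Pose:
    """A random valid pose with well-separated joints (no degenerate
    segments): joints scattered in a 2 m cube around a plausible stance."""
    while True:
        positions = {
            j: rng.uniform([-1.0, -1.0, 1.0], [1.0, 1.0, 3.0]) for j in JOINTS
        }
        # reject near-degenerate arm geometry so arccos oracles stay stable
        ok = True
        for side in ("left", "right"):
            s = positions[f"{side}_shoulder"]
            e = positions[f"{side}_elbow"]
            w = positions[f"{side}_wrist"]
            if (
                np.linalg.norm(e - s) < 1e-3
                or np.linalg.norm(w - e) < 1e-3
                or np.linalg.norm(s - e) < 1e-3
            ):
                ok = False
        if (
            np.linalg.norm(
                positions["right_shoulder"][[0, 2]] - positions["left_shoulder"][[0, 2]]
            )
            < 1e-3
        ):
            ok = False
        if ok:
            return Pose(
                time=0.0,
                positions=positions,
                valid={j: True for j in JOINTS},
            )
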