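"""Personalized regression calibration of tracker shoulder angles.

A calibration mapping is fitted separately for every stratum — one subject
× exercise × camera distance — from frame-level univariate pairs
(tracker-estimated shoulder angle, reference shoulder angle).  Ten
regressor families are compared: four linear models (ordinary least
squares, ridge, lasso, elastic net), a linear support-vector regressor,
and five nonlinear models (decision tree, random forest, gradient
boosting, cubic polynomial regression, RBF-kernel SVR).  Each stratum is
shuffled and split 80/20; errors (MAE/RMSE in degrees) are reported on the
held-out 20% alongside the uncalibrated identity-mapping baseline on the
same test indices.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR, LinearSVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "FAMILIES",
    "RegressorSpec",
    "CalibrationDataset",
    "CalibrationResult",
    "split_shuffle",
    "fit_calibrator",
    "evaluate_calibration",
    "run_model_comparison",
    "family_summary",
    "stratum_seed",
]

#: The ten regressor families, in the order they are reported.
FAMILIES: Tuple[str, ...] = (
    "LR",        # ordinary least squares
    "RR",        # ridge
    "LaR",       # lasso
    "ER",        # elastic net
    "SVR_linear",
    "DT",        # decision tree
    "RF",        # random forest
    "GB",        # gradient boosting
    "PR",        # polynomial (cubic) regression
    "SVR_RBF",
)

#: Linear families expected to behave near-identically with small penalties.
LINEAR_FAMILIES: Tuple[str, ...] = ("LR", "RR", "LaR", "ER")

_DEFAULT_HYPERPARAMS: Dict[str, Dict[str, object]] = {
    "LR": {},
    "RR": {"alpha": 1.0},
    "LaR": {"alpha": 0.01},
    "ER": {"alpha": 0.01, "l1_ratio": 0.5},
    "SVR_linear": {"C": 10.0, "epsilon": 0.1},
    "DT": {"max_depth": 6},
    "RF": {"n_estimators": 200, "max_depth": 8},
    "GB": {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 3},
    "PR": {"degree": 3},
    "SVR_RBF": {"C": 10.0, "gamma": "scale", "epsilon": 0.1},
}


@dataclass(frozen=True)
class RegressorSpec:
    """One regressor family with its hyperparameters and a fit seed."""

    family: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")

    def resolved_hyperparams(self) -> Dict[str, object]:
        hp = dict(_DEFAULT_HYPERPARAMS[self.family])
        hp.update(self.hyperparams)
        return hp


@dataclass
class CalibrationDataset:
    """Frame-level (tracker angle, reference angle) pairs of one stratum."""

    x: np.ndarray
    y: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass
class CalibrationResult:
    """Train/test errors of one family on one stratum, with the
    uncalibrated identity-mapping baseline on the same test indices."""

    spec: RegressorSpec
    train_mae: float
    test_mae: float
    train_rmse: float
    test_rmse: float
    baseline_test_mae: float
    baseline_test_rmse: float
    split_seed: int
    meta: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "family": self.spec.family,
            "train_mae": self.train_mae,
            "test_mae": self.test_mae,
            "train_rmse": self.train_rmse,
            "test_rmse": self.test_rmse,
            "baseline_test_mae": self.baseline_test_mae,
            "baseline_test_rmse": self.baseline_test_rmse,
            "split_seed": self.split_seed,
            **self.meta,
        }


def split_shuffle(
    dataset: CalibrationDataset, train_frac: float = 0.8, seed: int = 0
) -> Tuple[CalibrationDataset, CalibrationDataset]:
    """Reproducible shuffled train/test split of one stratum.

    Default 80% train / 20% test; sizes differ from the exact fraction by
    at most one sample.  Strata with fewer than 10 samples are rejected —
    too small to calibrate.
    """
    n = len(dataset)
    if n < 10:
        raise ValueError(f"stratum too small to calibrate (n={n} < 10)")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1) — both splits must be non-empty")
    idx_train, idx_test = train_test_split(
        np.arange(n), train_size=train_frac, shuffle=True, random_state=seed
    )
    mk = lambda idx: CalibrationDataset(
        dataset.x[idx], dataset.y[idx], dict(dataset.meta)
    )
    return mk(np.sort(idx_train)), mk(np.sort(idx_test))


def _make_estimator(spec: RegressorSpec):
    hp = spec.resolved_hyperparams()
    fam = spec.family
    if fam == "LR":
        return LinearRegression()
    if fam == "RR":
        return make_pipeline(StandardScaler(), Ridge(**hp))
    if fam == "LaR":
        return make_pipeline(StandardScaler(), Lasso(**hp, max_iter=10000))
    if fam == "ER":
        return make_pipeline(StandardScaler(), ElasticNet(**hp, max_iter=10000))
    if fam == "SVR_linear":
        return make_pipeline(
            StandardScaler(), LinearSVR(**hp, random_state=spec.seed, max_iter=10000)
        )
    if fam == "DT":
        return DecisionTreeRegressor(**hp, random_state=spec.seed)
    if fam == "RF":
        return RandomForestRegressor(**hp, random_state=spec.seed)
    if fam == "GB":
        return GradientBoostingRegressor(**hp, random_state=spec.seed)
    if fam == "PR":
        return make_pipeline(
            PolynomialFeatures(degree=int(hp["degree"]), include_bias=False),
            StandardScaler(),
            LinearRegression(),
        )
    if fam == "SVR_RBF":
        return make_pipeline(StandardScaler(), SVR(kernel="rbf", **hp))
    raise AssertionError(fam)


class FittedCalibrator:
    """A fitted univariate degrees → degrees mapping."""

    def __init__(self, spec: RegressorSpec, estimator) -> None:
        self.spec = spec
        self._estimator = estimator

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        return np.asarray(self._estimator.predict(x), dtype=float)


def fit_calibrator(spec: RegressorSpec, train: CalibrationDataset) -> FittedCalibrator:
    """Fit one regressor family on a training stratum.

    Raises on degenerate data (constant tracker angle: nothing to regress
    on), naming the stratum.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if np.ptp(train.x) == 0:
        raise ValueError(
            f"constant tracker angle in stratum {train.meta or '<unknown>'}: cannot fit"
        )
    est = _make_estimator(spec)
    est.fit(train.x.reshape(-1, 1), train.y)
    return FittedCalibrator(spec, est)


def _errors(pred: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    d = np.asarray(pred, float) - np.asarray(y, float)
    return float(np.mean(np.abs(d))), float(np.sqrt(np.mean(d**2)))


def evaluate_calibration(
    mapping: FittedCalibrator,
    train: CalibrationDataset,
    test: CalibrationDataset,
    split_seed: int = 0,
) -> CalibrationResult:
    """Errors of a fitted mapping on train and held-out test data, plus the
    uncalibrated baseline (identity mapping) on the same test samples."""
    train_mae, train_rmse = _errors(mapping(train.x), train.y)
    test_mae, test_rmse = _errors(mapping(test.x), test.y)
    base_mae, base_rmse = _errors(test.x, test.y)
    return CalibrationResult(
        spec=mapping.spec,
        train_mae=train_mae,
        test_mae=test_mae,
        train_rmse=train_rmse,
        test_rmse=test_rmse,
        baseline_test_mae=base_mae,
        baseline_test_rmse=base_rmse,
        split_seed=split_seed,
        meta=dict(test.meta),
    )


def stratum_seed(global_seed: int, stratum_key: str) -> int:
    """Deterministic per-stratum seed: CRC32 of the stratum key mixed with
    the global seed, reduced below 2**31."""
    return (global_seed * 1000003 + zlib.crc32(stratum_key.encode())) % (2**31)


def run_model_comparison(
    datasets: Iterable[CalibrationDataset],
    families: Sequence[str] = FAMILIES,
    train_frac: float = 0.8,
    global_seed: int = 0,
    hyperparams: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> pd.DataFrame:
    """Full stratum × family grid of calibration results.

    Every stratum is split once (seeded deterministically from
    ``global_seed`` and the stratum's identity) and all families are
    fitted on the identical split.  A stratum that fails (too small,
    degenerate) is recorded with an ``error`` column and skipped, not
    fatal.  Returns a long-format DataFrame, one row per stratum × family.
    """
    rows: List[Dict[str, object]] = []
    for ds in datasets:
        key = "|".join(
            str(ds.meta.get(k, "?")) for k in ("subject_id", "exercise", "distance", "arm")
        )
        seed = stratum_seed(global_seed, key)
        try:
            train, test = split_shuffle(ds, train_frac=train_frac, seed=seed)
            for fam in families:
                spec = RegressorSpec(
                    family=fam,
                    hyperparams=dict((hyperparams or {}).get(fam, {})),
                    seed=seed,
                )
                mapping = fit_calibrator(spec, train)
                res = evaluate_calibration(mapping, train, test, split_seed=seed)
                rows.append(res.to_dict())
        except ValueError as exc:
            rows.append({"family": None, "error": str(exc), **ds.meta})
    return pd.DataFrame(rows)


def family_summary(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-family mean ± sd (population) of test errors across strata."""
    ok = grid[grid["family"].notna()] if "family" in grid else grid
    if ok.empty:
        return pd.DataFrame()
    sd = lambda x: float(np.std(np.asarray(x, float), ddof=0))
    out = ok.groupby("family").agg(
        test_mae_mean=("test_mae", "mean"),
        test_mae_sd=("test_mae", sd),
        test_rmse_mean=("test_rmse", "mean"),
        test_rmse_sd=("test_rmse", sd),
        baseline_test_mae_mean=("baseline_test_mae", "mean"),
        baseline_test_rmse_mean=("baseline_test_rmse", "mean"),
        n_strata=("test_mae", "size"),
    )
    return out.reindex([f for f in FAMILIES if f in out.index]).reset_index()
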