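"""Agreement analysis between the tracker and the reference system.

Per aligned angle pair: MAE, RMSE, R² (squared Pearson correlation by
default — see :func:`agreement_metrics`), Spearman rank correlation, and
the mean/sd of the per-sample differences that parameterise a
Bland–Altman-style difference plot.  Across conditions: a Friedman test
over the three camera distances with Bonferroni-corrected post-hoc
Wilcoxon signed-rank pairs, a Wilcoxon test between left and right
shoulder angles, and Shapiro–Wilk / Kolmogorov–Smirnov normality checks on
the errors.

Standard deviations are population sds (divide by N) throughout, matching
the convention of the published demographic table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .angle_engine import AngleSeries
from .signal_prep import AlignedPair

__all__ = [
    "MetricReport",
    "DifferencePlotData",
    "StatTestReport",
    "agreement_metrics",
    "difference_plot_data",
    "distance_effect_test",
    "arm_difference_test",
    "normality_tests",
    "histogram_data",
    "aggregate_report",
]


@dataclass
class MetricReport:
    """Agreement statistics between two aligned angle traces (degrees)."""

    mae: float
    rmse: float
    r2: Optional[float]
    spearman: Optional[float]
    mean_diff: float
    sd_diff: float
    n: int
    meta: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        d = {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "spearman": self.spearman,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "n": self.n,
        }
        d.update(self.meta)
        return d


@dataclass
class DifferencePlotData:
    """Bland–Altman-style difference plot: per-sample method difference
    against the best estimate of the true value, with mean and mean±sd
    reference lines."""

    x: np.ndarray
    diff: np.ndarray
    mean_line: float
    upper_line: float
    lower_line: float


@dataclass
class StatTestReport:
    test_name: str
    statistic: float
    p_value: float
    groups: Tuple[str, ...] = ()
    posthoc: Optional[List["StatTestReport"]] = None


def _sd(x: np.ndarray) -> float:
    """Population standard deviation (divide by N)."""
    return float(np.std(np.asarray(x, float), ddof=0))


def agreement_metrics(pair: AlignedPair, r2_variant: str = "correlation") -> MetricReport:
    """Agreement battery for one aligned pair.

    ``r2_variant='correlation'`` (default) reports R² as the squared
    Pearson correlation between test and reference — the reading under
    which a trace can have a large constant bias (high MAE) yet R² near 1.
    ``'identity'`` reports 1 − SSres/SStot about the identity line instead.
    On constant input either correlation is undefined and reported as
    ``None`` with a warning.
    """
    if len(pair) == 0:
        raise ValueError("empty aligned pair")
    ref, test = pair.reference, pair.test
    diff = test - ref
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))

    r2: Optional[float]
    spearman: Optional[float]
    if np.ptp(ref) == 0 or np.ptp(test) == 0:
        warnings.warn(
            "constant series: correlation-based metrics undefined", RuntimeWarning
        )
        r2 = None
        spearman = None
    else:
        if r2_variant == "correlation":
            r2 = float(stats.pearsonr(test, ref).statistic ** 2)
        elif r2_variant == "identity":
            ss_res = float(np.sum(diff**2))
            ss_tot = float(np.sum((ref - ref.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot
        else:
            raise ValueError(f"unknown r2_variant {r2_variant!r}")
        spearman = float(stats.spearmanr(test, ref).statistic)

    return MetricReport(
        mae=mae,
        rmse=rmse,
        r2=r2,
        spearman=spearman,
        mean_diff=float(np.mean(diff)),
        sd_diff=_sd(diff),
        n=len(pair),
        meta={"angle": pair.angle_name, "arm": pair.arm, **pair.meta},
    )


def difference_plot_data(pair: AlignedPair) -> DifferencePlotData:
    """Difference-plot coordinates: x = per-sample mean of the two methods
    (best estimate of the true value), diff = test − reference, with
    mean(diff) and mean ± sd(diff) lines."""
    if len(pair) == 0:
        raise ValueError("empty aligned pair")
    diff = pair.test - pair.reference
    m, s = float(np.mean(diff)), _sd(diff)
    return DifferencePlotData(
        x=(pair.test + pair.reference) / 2.0,
        diff=diff,
        mean_line=m,
        upper_line=m + s,
        lower_line=m - s,
    )


def distance_effect_test(
    values_by_distance: Mapping[float, Sequence[float]],
    alpha_level: float = 0.05,
) -> StatTestReport:
    """Friedman test of a distance effect on matched per-unit values (one
    value per subject/trial at each of the three camera distances), with
    Bonferroni-corrected post-hoc pairwise Wilcoxon signed-rank tests.

    Requires the same matched-unit count per distance and at least 3 units.
    """
    distances = sorted(values_by_distance)
    if len(distances) < 3:
        raise ValueError("need at least 3 distance conditions")
    cols = [np.asarray(values_by_distance[d], float) for d in distances]
    n_units = {c.size for c in cols}
    if len(n_units) != 1:
        raise ValueError("matched design: every distance needs the same unit count")
    if cols[0].size < 3:
        raise ValueError("need at least 3 matched units")

    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        stat, p = 0.0, 1.0  # identical columns carry no distance effect
    else:
        stat, p = stats.friedmanchisquare(*cols)

    pairs = list(combinations(range(len(distances)), 2))
    posthoc = []
    for i, j in pairs:
        res = _wilcoxon(cols[i], cols[j])
        posthoc.append(
            StatTestReport(
                test_name="wilcoxon_signed_rank",
                statistic=res[0],
                p_value=min(1.0, res[1] * len(pairs)),  # Bonferroni
                groups=(str(distances[i]), str(distances[j])),
            )
        )
    return StatTestReport(
        test_name="friedman",
        statistic=float(stat),
        p_value=float(p),
        groups=tuple(str(d) for d in distances),
        posthoc=posthoc,
    )


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    d = np.asarray(a, float) - np.asarray(b, float)
    if np.all(d == 0):
        return 0.0, 1.0  # degenerate: no information against the null
    res = stats.wilcoxon(a, b)
    return float(res.statistic), float(res.pvalue)


def arm_difference_test(
    alpha_left: Sequence[float], alpha_right: Sequence[float]
) -> StatTestReport:
    """Wilcoxon signed-rank test between matched left- and right-shoulder
    angle samples.  All-zero differences report p = 1 by convention."""
    a = np.asarray(alpha_left, float)
    b = np.asarray(alpha_right, float)
    if a.size != b.size:
        raise ValueError("matched pairs required")
    stat, p = _wilcoxon(a, b)
    return StatTestReport(
        test_name="wilcoxon_signed_rank", statistic=stat, p_value=p, groups=("L", "R")
    )


def normality_tests(errors: Sequence[float]) -> List[StatTestReport]:
    """Shapiro–Wilk and Kolmogorov–Smirnov normality checks on an error
    sample.  The KS test compares against a normal with the sample's own
    mean and (population) sd.  A constant sample has no scale: both tests
    are reported with NaN statistic and p = 0 (normality clearly not
    assessable as satisfied)."""
    x = np.asarray(errors, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        return [
            StatTestReport(name, float("nan"), 0.0)
            for name in ("shapiro_wilk", "kolmogorov_smirnov")
        ]
    # Shapiro–Wilk is unreliable (and warns) above n=5000: thin evenly
    xs = x[:: max(1, x.size // 5000 + (x.size % 5000 > 0))] if x.size > 5000 else x
    sw = stats.shapiro(xs)
    ks = stats.kstest(x, "norm", args=(float(np.mean(x)), _sd(x)))
    return [
        StatTestReport("shapiro_wilk", float(sw.statistic), float(sw.pvalue)),
        StatTestReport("kolmogorov_smirnov", float(ks.statistic), float(ks.pvalue)),
    ]


def histogram_data(
    series: AngleSeries | np.ndarray,
    bin_width: float = 5.0,
    angle: str = "alpha",
) -> Tuple[np.ndarray, np.ndarray]:
    """Counts of angle samples over [0, 180] with the given bin width.

    Returns ``(counts, bin_edges)``; counts sum to the sample count.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    values = series.angle(angle) if isinstance(series, AngleSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ValueError("empty sample")
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    if edges[-1] < 180.0:
        edges = np.append(edges, 180.0)
    counts, edges = np.histogram(np.clip(values, 0.0, 180.0), bins=edges)
    return counts, edges


def aggregate_report(
    reports: Iterable[MetricReport],
    grouping: Sequence[str] = ("angle", "arm", "distance"),
) -> pd.DataFrame:
    """Mean ± sd table of agreement metrics across subjects.

    One row per group (e.g. angle × arm × distance) with columns
    ``<metric>_mean`` and ``<metric>_sd`` (population sd) for each metric,
    plus the number of contributing reports.  Groups with no reports are
    simply absent; a warning is emitted if nothing aggregates at all.
    """
    rows = [r.to_dict() for r in reports]
    if not rows:
        warnings.warn("no reports to aggregate", RuntimeWarning)
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    metrics = [c for c in ("mae", "rmse", "r2", "spearman", "mean_diff", "sd_diff") if c in df]
    keys = [g for g in grouping if g in df.columns]
    if not keys:
        raise ValueError("no grouping keys present in reports")
    agg = df.groupby(keys, dropna=False)[metrics].agg(
        ["mean", lambda x: float(np.std(np.asarray(x, float), ddof=0))]
    )
    agg.columns = [f"{m}_{'mean' if f == 'mean' else 'sd'}" for m, f in agg.columns]
    agg["n_reports"] = df.groupby(keys, dropna=False).size()
    return agg.reset_index()
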