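"""Resampling and temporal alignment of angle traces from two systems.

The reference stream (256 fps) and the tracker stream (30 fps) must be
compared sample-by-sample.  Both are linearly interpolated onto a common
uniform grid at the slower rate, then the residual timing offset between
the systems is estimated by maximising the cross-correlation of the
mean-removed shoulder-angle traces; the same integer-frame lag is applied
to all three angles of the trial.  Alignment never alters sample values,
only indexing and trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .angle_engine import AngleSeries

__all__ = ["AlignedPair", "resample", "estimate_lag", "synchronize"]

DEFAULT_COMPARISON_FPS = 30.0

_ANGLES = ("alpha", "beta", "gamma")


@dataclass
class AlignedPair:
    """Matched reference/test samples of one angle on a common time grid."""

    time: np.ndarray
    reference: np.ndarray
    test: np.ndarray
    angle_name: str
    arm: str
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if not (self.time.size == self.reference.size == self.test.size):
            raise ValueError("aligned arrays must have equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)


def resample(series: AngleSeries, target_fps: float) -> AngleSeries:
    """Linear interpolation of an angle series onto a uniform grid at
    ``target_fps`` spanning the series' own time range (no extrapolation)."""
    if len(series) < 2:
        raise ValueError("cannot resample a series with fewer than 2 samples")
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    t0, t1 = series.times[0], series.times[-1]
    n = int(np.floor((t1 - t0) * target_fps)) + 1
    t = t0 + np.arange(n) / target_fps
    interp = {a: np.interp(t, series.times, series.angle(a)) for a in _ANGLES}
    # a resampled frame counts as filled if either bracketing source frame was
    filled = np.interp(t, series.times, series.filled.astype(float)) > 0
    return AngleSeries(
        times=t,
        alpha=interp["alpha"],
        beta=interp["beta"],
        gamma=interp["gamma"],
        arm=series.arm,
        fps=target_fps,
        filled=filled,
        meta=dict(series.meta),
    )


def estimate_lag(
    reference: np.ndarray, test: np.ndarray, fps: float, max_lag: float
) -> int:
    """Integer-frame lag of ``test`` relative to ``reference`` maximising
    the normalized cross-correlation (per-window mean-removed, unit-scaled)
    over ±``max_lag`` seconds.  Ties (e.g. constant signals, where every
    correlation is undefined and scored 0) break toward the smallest |lag|,
    then toward the negative lag."""
    r = np.asarray(reference, float)
    s = np.asarray(test, float)
    max_shift = int(round(max_lag * fps))
    lags = np.arange(-max_shift, max_shift + 1)
    scores = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = r[k:], s[: s.size - k]
        else:
            a, b = r[: r.size + k], s[-k:]
        m = min(a.size, b.size)
        if m < 2:
            scores[i] = -np.inf
            continue
        a = a[:m] - a[:m].mean()
        b = b[:m] - b[:m].mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        scores[i] = np.dot(a, b) / denom if denom > 0 else 0.0
    best = np.max(scores)
    candidates = lags[scores >= best - 1e-12 * max(1.0, abs(best))]
    return int(candidates[np.lexsort((candidates, np.abs(candidates)))[0]])


def synchronize(
    reference: AngleSeries,
    test: AngleSeries,
    max_lag: float = 2.0,
) -> Dict[str, AlignedPair]:
    """Align two same-rate angle series and return one :class:`AlignedPair`
    per angle (keys ``alpha``, ``beta``, ``gamma``).

    The lag is estimated once from the shoulder-angle (alpha) traces and
    applied identically to all three angles; both series are trimmed to
    their overlap.  Timestamps play no role in the estimate — only the
    signal content does, which is the point of synchronizing by
    cross-correlation.  Sign convention: test sample ``i`` matches
    reference sample ``i + lag``, so a stream whose content is *delayed*
    yields a negative lag.
    """
    if abs(reference.fps - test.fps) > 1e-9:
        raise ValueError("series must share a common fps before alignment; resample first")
    fps = reference.fps
    nr, nt = len(reference), len(test)
    m = min(nr, nt)
    lag = estimate_lag(reference.alpha[:m], test.alpha[:m], fps, max_lag)

    # test sample i corresponds to reference sample i + lag
    ref_start, test_start = max(lag, 0), max(-lag, 0)
    n = min(nr - ref_start, nt - test_start)
    # overlap must cover at least one repetition (when the trial says how long
    # a repetition is), otherwise at least two samples
    rep = reference.meta.get("rep_duration")
    min_n = max(2, int(np.ceil(float(rep) * fps)) if rep else 2)
    if n < min_n:
        raise ValueError(
            f"overlap after alignment ({n} frames) shorter than one repetition"
        )

    time = reference.times[ref_start : ref_start + n]
    pairs: Dict[str, AlignedPair] = {}
    for a in _ANGLES:
        pairs[a] = AlignedPair(
            time=time.copy(),
            reference=reference.angle(a)[ref_start : ref_start + n],
            test=test.angle(a)[test_start : test_start + n],
            angle_name=a,
            arm=reference.arm,
            meta={**reference.meta, "lag_frames": lag, "lag_s": lag / fps,
                  "test_filled": test.filled[test_start : test_start + n]},
        )
    return pairs
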