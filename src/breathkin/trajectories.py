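"""Whole-cycle trajectory extraction and cross-correlation similarity.

For the dynamic comparison, each breathing cycle is cut from its channel
with a +-1.5 s pad around the cycle (inhalation onset - pad to exhalation
offset + pad), using the *reference channel's* landmarks for every channel
of the utterance so all channels share one window.  Windows are then
resampled to 50 equally spaced steps for the Gaussian-process contrast, and
whole-trajectory similarity between channel pairs is parameterized by the
maximum normalized cross-correlation over lags within +-0.5 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import TimeSeries
from .errors import DegenerateInputError
from .landmarks import BreathingLandmarks

log = logging.getLogger(__name__)

__all__ = [
    "CycleTrajectory",
    "extract_cycle_window",
    "resample_to_steps",
    "max_cross_correlation",
]


@dataclass(frozen=True)
class CycleTrajectory:
    """One cycle's shape at fixed, equally spaced steps."""

    steps: np.ndarray
    channel: str = ""
    utterance_id: str = ""
    speaker: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.steps, dtype=float)
        if arr.ndim != 1 or not np.all(np.isfinite(arr)):
            raise ValueError("trajectory steps must be a finite 1-D vector")
        object.__setattr__(self, "steps", arr)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def extract_cycle_window(
    ts: TimeSeries, lm_ref: BreathingLandmarks, pad_s: float = 1.5
) -> TimeSeries:
    """Sub-series over [inhalation onset - pad, exhalation offset + pad].

    Landmarks come from the designated reference channel and are applied
    unchanged to every channel of the utterance.  The window is clipped to
    the signal support (with a logged note); an empty intersection raises.
    """
    if lm_ref.flagged:
        raise DegenerateInputError("cannot window a cycle with no inhalation")
    t0 = lm_ref.inhalation_onset_s - pad_s
    t1 = lm_ref.exhalation_offset_s + pad_s
    if t0 < ts.start_s - ts.dt / 2 or t1 > ts.end_s + ts.dt / 2:
        log.info(
            "%s: cycle window [%.3f, %.3f] clipped to support [%.3f, %.3f]",
            ts.label, t0, t1, ts.start_s, ts.end_s,
        )
    return ts.slice_time(t0, t1)


def resample_to_steps(ts: TimeSeries, n_steps: int = 50, **ids) -> CycleTrajectory:
    """Linear interpolation at ``n_steps`` equally spaced times spanning the
    window inclusive of both ends."""
    if len(ts) < 2:
        raise DegenerateInputError("resample_to_steps needs at least 2 samples")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    grid = np.linspace(ts.start_s, ts.end_s, n_steps)
    vals = np.interp(grid, ts.times(), ts.values)
    return CycleTrajectory(vals, channel=ids.get("channel", ts.label),
                           utterance_id=ids.get("utterance_id", ""),
                           speaker=ids.get("speaker", ""))


def max_cross_correlation(
    a: TimeSeries,
    b: TimeSeries,
    max_lag_s: float = 0.5,
    min_overlap: int = 10,
) -> tuple[float, float]:
    """Maximum normalized cross-correlation between two signals over lags.

    For each integer lag within ``+-max_lag_s`` on the common grid, the
    Pearson correlation of the overlapping segments is computed with the
    segments' own means and SDs (local normalization, avoiding edge bias).
    Returns ``(coefficient, lag_s)`` at the maximum; a positive lag means
    ``b`` trails ``a``.  Lags with fewer than ``min_overlap`` overlapping
    samples, or a zero-variance segment, are skipped; if no lag qualifies,
    a :class:`DegenerateInputError` is raised.
    """
    if abs(a.rate_hz - b.rate_hz) > 1e-9:
        raise ValueError("signals must share one sampling rate")
    rate = a.rate_hz
    base = int(round((b.start_s - a.start_s) * rate))
    max_lag = int(round(max_lag_s * rate))
    xa, xb = a.values, b.values
    na, nb = len(xa), len(xb)

    best_r = -np.inf
    best_lag = 0.0
    for lag in range(-max_lag, max_lag + 1):
        # compare a[i] with b[j] where j = i - base + lag  (b shifted by lag)
        shift = lag - base
        i0 = max(0, -shift)
        i1 = min(na, nb - shift)
        if i1 - i0 < min_overlap:
            continue
        seg_a = xa[i0:i1]
        seg_b = xb[i0 + shift : i1 + shift]
        sa = seg_a - seg_a.mean()
        sb = seg_b - seg_b.mean()
        denom = np.sqrt(np.dot(sa, sa) * np.dot(sb, sb))
        if denom == 0.0:
            continue
        r = float(np.dot(sa, sb) / denom)
        if r > best_r:
            best_r = r
            best_lag = lag / rate
    if not np.isfinite(best_r):
        raise DegenerateInputError(
            f"no lag with >= {min_overlap} overlapping samples and variance"
        )
    return best_r, best_lag
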