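"""Independent exhaustive-scan landmark oracle.

Implements the documented landmark rule with plain Python loops over every
sample — no vectorized shortcuts shared with the production detector — so
the two can be compared exactly on arbitrary signals.
"""

from __future__ import annotations

import math

from breathkin.core import TimeSeries
from breathkin.landmarks import BreathingLandmarks, DetectionConfig, NO_INHALATION


def oracle_velocity(values, dt: float) -> list[float]:
    """Central differences, one-sided first-order at the edges."""
    n = len(values)
    v = [0.0] * n
    v[0] = (values[1] - values[0]) / dt
    v[n - 1] = (values[n - 1] - values[n - 2]) / dt
    for i in range(1, n - 1):
        v[i] = (values[i + 1] - values[i - 1]) / (2.0 * dt)
    return v


def oracle_landmarks(
    ts: TimeSeries,
    acoustic_onset_s: float,
    acoustic_offset_s: float,
    cfg: DetectionConfig,
) -> BreathingLandmarks:
    """Brute-force scan: explicit loops for the peak search, the floor
    crossings on both sides, and the exhalation-window minimum."""
    assert cfg.min_velocity_peak is not None, "oracle requires an explicit QC threshold"
    values = [float(x) for x in ts.values]
    n = len(values)
    dt = 1.0 / ts.rate_hz
    v = oracle_velocity(values, dt)

    def idx(t: float) -> int:
        i = int(round((t - ts.start_s) * ts.rate_hz))
        return 0 if i < 0 else (n - 1 if i > n - 1 else i)

    half = cfg.peak_window_s / 2.0
    w0, w1 = idx(acoustic_onset_s - half), idx(acoustic_onset_s + half)
    peak = w0
    for i in range(w0, w1 + 1):
        if v[i] > v[peak]:  # strict: ties keep the earlier sample
            peak = i
    vmax = v[peak]
    def t_at(i: int) -> float:
        # same arithmetic as the production detector: start + i / rate
        return ts.start_s + i / ts.rate_hz

    if vmax <= max(cfg.min_velocity_peak, 0.0):
        return BreathingLandmarks(math.nan, math.nan, math.nan, t_at(peak),
                                  qc_flags=frozenset({NO_INHALATION}))

    floor = cfg.zero_frac * vmax
    onset = None
    for i in range(peak, -1, -1):
        if v[i] <= floor:
            onset = i
            break
    if onset is None:
        onset = w0

    off = None
    for i in range(peak + 1, n):
        if v[i] <= floor:
            off = i
            break
    if off is None:
        off = n - 1

    e0 = peak + 1 if peak + 1 < n else n - 1
    e1 = idx(acoustic_offset_s + cfg.tail_extension_s)
    if e1 < e0:
        e1 = e0
    exh = e0
    for i in range(e0, e1 + 1):
        if values[i] < values[exh]:
            exh = i

    return BreathingLandmarks(t_at(onset), t_at(off), t_at(exh), t_at(peak))
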