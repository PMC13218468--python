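"""Signal conditioning: normalization, resampling, Gaussian filtering, and
clapperboard-based synchronization.

The canonical conditioning chain for a breathing channel is

    extract -> max-abs normalize -> resample to 100 Hz -> Gaussian filter (sigma = 5 samples)

i.e. the filter sigma is 5 samples *at the analysis rate* (50 ms at 100 Hz).
Resampling is polyphase rational resampling with a Kaiser-windowed low-pass
(anti-aliasing when downsampling); filter edges use reflect padding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal

from .core import TimeSeries
from .errors import AlignmentError, DegenerateInputError, DetectionError

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "normalize_amplitude",
    "resample",
    "gaussian_smooth",
    "preprocess",
    "detect_sync_impulse",
    "align_streams",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    target_rate_hz : analysis sampling rate (default 100 Hz)
    gaussian_sigma_samples : filter sigma in samples at the analysis rate
        (default 5, i.e. 50 ms at 100 Hz); 0 disables filtering
    normalize : divide by max |value| before resampling
    sync_window_s : leading window searched for the clapperboard impulse
    sync_threshold_frac : impulse threshold as a fraction of the window max
    """

    target_rate_hz: float = 100.0
    gaussian_sigma_samples: float = 5.0
    normalize: bool = True
    sync_window_s: float = 5.0
    sync_threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.target_rate_hz <= 0:
            raise ValueError("target_rate_hz must be positive")
        if self.gaussian_sigma_samples < 0:
            raise ValueError("gaussian_sigma_samples must be >= 0")


def normalize_amplitude(ts: TimeSeries) -> TimeSeries:
    """Divide every sample by max |value| so that max |output| is exactly 1.

    Shape-preserving (output = input x positive scalar) and idempotent.
    Raises :class:`DegenerateInputError` on an all-zero signal.
    """
    peak = float(np.max(np.abs(ts.values)))
    if peak == 0.0:
        raise DegenerateInputError(f"cannot normalize all-zero signal {ts.label!r}")
    return ts.with_values(ts.values / peak, units="norm")


def resample(ts: TimeSeries, target_rate_hz: float) -> TimeSeries:
    """Polyphase rational resampling with a Kaiser-windowed low-pass.

    The rational ratio is the exact reduced fraction of
    ``target_rate_hz / rate_hz`` (denominator capped at 10^6).  Output
    duration matches input duration to within one output sample.
    """
    if target_rate_hz <= 0:
        raise ValueError("target rate must be positive")
    if abs(target_rate_hz - ts.rate_hz) < 1e-12:
        return ts
    frac = Fraction(target_rate_hz / ts.rate_hz).limit_denominator(1_000_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(ts.values, up, down, window=("kaiser", 5.0),
                               padtype="line")
    return ts.with_values(out, rate_hz=ts.rate_hz * up / down)


def gaussian_smooth(ts: TimeSeries, sigma_samples: float) -> TimeSeries:
    """1-D Gaussian kernel filter with reflect padding.

    Unit DC gain (a constant signal is unchanged); ``sigma_samples = 0`` is
    the identity; output length equals input length.
    """
    if sigma_samples < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_samples == 0:
        return ts
    out = ndimage.gaussian_filter1d(ts.values, sigma=sigma_samples, mode="reflect")
    return ts.with_values(out)


def preprocess(ts: TimeSeries, cfg: PreprocessConfig | None = None) -> TimeSeries:
    """Apply the full conditioning chain: normalize -> resample -> smooth."""
    cfg = cfg or PreprocessConfig()
    out = ts
    if cfg.normalize:
        out = normalize_amplitude(out)
    out = resample(out, cfg.target_rate_hz)
    out = gaussian_smooth(out, cfg.gaussian_sigma_samples)
    log.debug(
        "preprocess %s: %d @ %.6g Hz -> %d @ %.6g Hz (sigma=%g)",
        ts.label, len(ts), ts.rate_hz, len(out), out.rate_hz,
        cfg.gaussian_sigma_samples,
    )
    return out


def detect_sync_impulse(
    audio: TimeSeries,
    threshold_frac: float = 0.8,
    search_window_s: float | None = 5.0,
) -> float:
    """Locate the clapperboard impulse in an audio track.

    Returns the time of the first sample whose absolute value reaches
    ``threshold_frac`` x the maximum absolute value within the search
    window.  The search is restricted to the leading ``search_window_s``
    seconds (the clap is produced at the beginning of the recording), which
    keeps later speech from masking the impulse.
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must lie in (0, 1]")
    win = audio
    if search_window_s is not None:
        win = audio.slice_time(audio.start_s, audio.start_s + search_window_s)
    mags = np.abs(win.values)
    peak = float(mags.max())
    if peak == 0.0:
        raise DetectionError(f"no impulse: audio track {audio.label!r} is silent")
    idx = int(np.argmax(mags >= threshold_frac * peak))
    return win.time_at(idx)


def align_streams(
    a: TimeSeries, b: TimeSeries, t_sync_a: float, t_sync_b: float
) -> tuple[TimeSeries, TimeSeries]:
    """Re-time two streams so the shared sync event is t = 0, then trim both
    to their common support.

    Raises :class:`AlignmentError` if the shifted streams do not overlap.
    """
    for ts, t_sync in ((a, t_sync_a), (b, t_sync_b)):
        if not (ts.start_s - ts.dt / 2 <= t_sync <= ts.end_s + ts.dt / 2):
            raise AlignmentError(
                f"sync time {t_sync} s outside support of {ts.label!r}"
            )
    a2 = a.shifted(-t_sync_a)
    b2 = b.shifted(-t_sync_b)
    lo = max(a2.start_s, b2.start_s)
    hi = min(a2.end_s, b2.end_s)
    if hi <= lo:
        raise AlignmentError("no common support after synchronization")
    return a2.slice_time(lo, hi), b2.slice_time(lo, hi)
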