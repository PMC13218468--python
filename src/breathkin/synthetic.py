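"""Synthetic recording sessions with known ground truth.

A session is driven by one latent breathing trajectory ``b(t)``: a sum of
per-cycle kernels, each with a rapid raised-cosine inhalation rise followed
by a prolonged, smooth exhalation decay — the asymmetric shape of speech
breathing (tidal breathing uses symmetric, lower-amplitude cycles).  From
the latent the generator derives:

* a RIP-style thoracic band channel  = ``rip_gain * b + noise`` at the RIP
  rate (default 44.1 kHz);
* five EMA sensors (reference, sternum, chest mid/left/right) whose x and y
  coordinates couple to the latent with per-sensor gains plus independent
  noise and slow linear drift, at the EMA rate (default 1250 Hz); the
  reference sensor carries baseline + noise only;
* two audio tracks, each holding exactly one clapperboard-like impulse,
  offset between the systems by a known inter-system clock offset;
* a Praat-style interval tier with one utterance ("Sonja ...") per cycle,
  whose acoustic onset trails the inhalation onset by a known lag;
* ground-truth landmark times for every cycle.

Kernel shape: the inhalation is a raised-cosine rise (zero slope at onset
and at the peak); the exhalation is a **quarter-cosine** decay — zero slope
at the peak, maximal slope at the terminal trough.  A decay that lands with
zero slope would leave the exhalation-offset minimum flat over several
filter widths after Gaussian smoothing, making the terminal trough
ill-defined under noise; the quarter-cosine keeps it a genuine V-shaped
minimum.  The shape is isolated in :func:`breathing_kernel` and swappable.

All randomness flows from ``SessionSpec.seed``; a fixed seed yields a
bit-identical session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import Interval, IntervalTier, TimeSeries
from .distances import SENSOR_ROLES, SensorFrameSet
from .errors import SpecError
from .landmarks import BreathingLandmarks

__all__ = [
    "CycleSpec",
    "SessionSpec",
    "SyntheticSession",
    "breathing_kernel",
    "latent_trajectory",
    "generate_session",
    "speech_session",
    "tidal_session",
    "DEFAULT_SENSOR_GAINS",
    "DEFAULT_SENSOR_BASELINES",
]


@dataclass(frozen=True)
class CycleSpec:
    """One breathing cycle: onset time, phase durations, latent amplitude."""

    onset_s: float
    inhale_dur_s: float
    exhale_dur_s: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.inhale_dur_s <= 0 or self.exhale_dur_s <= 0:
            raise SpecError("cycle durations must be positive")
        if self.amplitude <= 0:
            raise SpecError("cycle amplitude must be positive")

    @property
    def peak_s(self) -> float:
        return self.onset_s + self.inhale_dur_s

    @property
    def end_s(self) -> float:
        return self.peak_s + self.exhale_dur_s


# x-gain in mm per latent unit; y-gain defaults to half the x-gain because
# vertical chest motion tracks breathing more weakly (and more variably)
# than the front-back expansion.
DEFAULT_SENSOR_GAINS: Mapping[str, tuple[float, float]] = {
    "ref": (0.0, 0.0),
    "sternum": (4.0, 2.0),
    "chestmid": (6.0, 3.0),
    "chestleft": (5.0, 2.5),
    "chestright": (5.0, 2.5),
}

# resting sensor positions in device coordinates, mm
DEFAULT_SENSOR_BASELINES: Mapping[str, tuple[float, float, float]] = {
    "ref": (50.0, -30.0, 0.0),
    "sternum": (80.0, -10.0, 0.0),
    "chestmid": (85.0, -5.0, 0.0),
    "chestleft": (80.0, -5.0, 40.0),
    "chestright": (80.0, -5.0, -40.0),
}


@dataclass(frozen=True)
class SessionSpec:
    """Full recording-session specification.

    Rates default to the devices they emulate (RIP 44.1 kHz, EMA 1250 Hz);
    noise SDs are i.i.d. Gaussian per sample at the native rate, in latent
    units for the RIP channel and mm for the sensors.  ``sync_offset_s`` is
    the EMA clock minus the RIP clock: an event at RIP-clock time t appears
    at EMA-clock time t + sync_offset_s.
    """

    cycles: tuple[CycleSpec, ...]
    rip_gain: float = 1.0
    rip_noise_sd: float = 0.0
    sensor_gains: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SENSOR_GAINS))
    sensor_baselines: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SENSOR_BASELINES))
    sensor_noise_sd: float = 0.0
    drift_per_s: float = 0.0
    rip_rate_hz: float = 44100.0
    ema_rate_hz: float = 1250.0
    sync_offset_s: float = 0.0
    sonja_lag_s: float = 0.5
    clap_time_s: float = 0.25
    tail_s: float = 1.0
    annotate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rip_rate_hz <= 0 or self.ema_rate_hz <= 0:
            raise SpecError("sampling rates must be positive")
        if self.rip_noise_sd < 0 or self.sensor_noise_sd < 0:
            raise SpecError("noise SDs must be >= 0")
        cycles = tuple(sorted(self.cycles, key=lambda c: c.onset_s))
        for a, b in zip(cycles, cycles[1:]):
            if b.onset_s < a.end_s - 1e-9:
                raise SpecError(
                    f"cycles overlap: one ends at {a.end_s:.3f} s, next starts "
                    f"at {b.onset_s:.3f} s"
                )
        object.__setattr__(self, "cycles", cycles)
        if not cycles:
            raise SpecError("a session needs at least one cycle")

    @property
    def duration_s(self) -> float:
        return self.cycles[-1].end_s + self.tail_s


@dataclass
class SyntheticSession:
    """Generated session: signals, annotations, and ground truth.

    Truth landmark times are on the RIP clock; subtract ``spec.clap_time_s``
    to express them in the post-synchronization frame (clap at t = 0).
    """

    spec: SessionSpec
    rip: TimeSeries
    sensors: SensorFrameSet
    audio_rip: TimeSeries
    audio_ema: TimeSeries
    annotations: IntervalTier
    truth: list[BreathingLandmarks]

    def truth_aligned(self) -> list[BreathingLandmarks]:
        """Ground-truth landmarks in the clap-at-zero frame."""
        dt = -self.spec.clap_time_s
        return [
            replace(
                lm,
                inhalation_onset_s=lm.inhalation_onset_s + dt,
                inhalation_offset_s=lm.inhalation_offset_s + dt,
                exhalation_offset_s=lm.exhalation_offset_s + dt,
                velocity_peak_s=lm.velocity_peak_s + dt,
            )
            for lm in self.truth
        ]


def breathing_kernel(spec: CycleSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Latent contribution of one cycle at time(s) ``t``.

    Zero before the onset and after the cycle end; raised-cosine rise from 0
    to ``amplitude`` over the inhalation; quarter-cosine decay back to 0
    over the exhalation.  Continuous everywhere, maximal exactly at the
    inhalation offset.
    """
    scalar = np.isscalar(t)
    tt = np.asarray(t, dtype=float)
    out = np.zeros_like(tt)
    o, d, e, a = spec.onset_s, spec.inhale_dur_s, spec.exhale_dur_s, spec.amplitude
    rise = (tt >= o) & (tt <= o + d)
    out[rise] = 0.5 * a * (1.0 - np.cos(np.pi * (tt[rise] - o) / d))
    fall = (tt > o + d) & (tt < o + d + e)
    out[fall] = a * np.cos(0.5 * np.pi * (tt[fall] - o - d) / e)
    return float(out[()]) if scalar else out


def latent_trajectory(cycles: Sequence[CycleSpec], t: np.ndarray) -> np.ndarray:
    """Sum of cycle kernels, evaluated efficiently on a sorted time grid."""
    out = np.zeros_like(t, dtype=float)
    for c in cycles:
        i0, i1 = np.searchsorted(t, [c.onset_s, c.end_s])
        if i1 > i0:
            out[i0:i1] += breathing_kernel(c, t[i0:i1])
    return out


def _impulse(track: np.ndarray, rate_hz: float, t_s: float) -> None:
    """Insert a short clapperboard-like burst (one impulse) in place."""
    i = int(round(t_s * rate_hz))
    n = len(track)
    burst = [1.0, -0.8, 0.6, -0.4, 0.2]
    for k, v in enumerate(burst):
        if 0 <= i + k < n:
            track[i + k] = v


def generate_session(spec: SessionSpec) -> SyntheticSession:
    """Generate one synthetic recording session from its specification."""
    rng = np.random.default_rng(spec.seed)
    T = spec.duration_s

    # RIP channel (RIP clock)
    n_rip = int(round(T * spec.rip_rate_hz)) + 1
    t_rip = np.arange(n_rip) / spec.rip_rate_hz
    rip_vals = spec.rip_gain * latent_trajectory(spec.cycles, t_rip)
    if spec.rip_noise_sd > 0:
        rip_vals = rip_vals + rng.normal(0.0, spec.rip_noise_sd, n_rip)
    rip = TimeSeries(rip_vals, spec.rip_rate_hz, 0.0, label="rip", units="au")

    # EMA sensors (EMA clock: physical time = ema_time - sync_offset_s)
    n_ema = int(round(T * spec.ema_rate_hz)) + 1
    t_ema = np.arange(n_ema) / spec.ema_rate_hz
    b_ema = latent_trajectory(spec.cycles, t_ema - spec.sync_offset_s)
    sensors: dict[str, dict[str, TimeSeries]] = {}
    for role in SENSOR_ROLES:
        gx, gy = spec.sensor_gains.get(role, (0.0, 0.0))
        bx, by, bz = spec.sensor_baselines.get(role, (0.0, 0.0, 0.0))
        coords: dict[str, TimeSeries] = {}
        for dim, base, gain in (("x", bx, gx), ("y", by, gy), ("z", bz, 0.0)):
            vals = np.full(n_ema, base, dtype=float)
            if role != "ref":
                vals += gain * b_ema + spec.drift_per_s * t_ema
            if spec.sensor_noise_sd > 0:
                vals = vals + rng.normal(0.0, spec.sensor_noise_sd, n_ema)
            coords[dim] = TimeSeries(vals, spec.ema_rate_hz, 0.0,
                                     label=f"{role}_{dim}", units="mm")
        sensors[role] = coords
    frames = SensorFrameSet(sensors)

    # audio tracks: exactly one impulse each, offset by the inter-system lag
    audio_rip_vals = np.zeros(n_rip)
    _impulse(audio_rip_vals, spec.rip_rate_hz, spec.clap_time_s)
    audio_rip = TimeSeries(audio_rip_vals, spec.rip_rate_hz, 0.0,
                           label="audio_rip", units="au")
    audio_ema_vals = np.zeros(n_rip)
    _impulse(audio_ema_vals, spec.rip_rate_hz, spec.clap_time_s + spec.sync_offset_s)
    audio_ema = TimeSeries(audio_ema_vals, spec.rip_rate_hz, 0.0,
                           label="audio_ema", units="au")

    # one utterance interval per cycle (RIP clock); the acoustic onset of
    # "Sonja" trails the inhalation onset by the configured lag
    intervals: list[Interval] = []
    if spec.annotate:
        for k, c in enumerate(spec.cycles):
            a_on = c.onset_s + spec.sonja_lag_s
            a_off = c.end_s - 0.05 * c.exhale_dur_s
            if a_off <= a_on:
                raise SpecError(
                    f"cycle {k}: sonja_lag_s {spec.sonja_lag_s} leaves no room "
                    "for the utterance within the exhalation"
                )
            intervals.append(Interval(a_on, a_off, "Sonja"))
    annotations = IntervalTier("sentence", intervals)

    truth = [
        BreathingLandmarks(
            inhalation_onset_s=c.onset_s,
            inhalation_offset_s=c.peak_s,
            exhalation_offset_s=c.end_s,
            velocity_peak_s=c.onset_s + 0.5 * c.inhale_dur_s,
        )
        for c in spec.cycles
    ]
    return SyntheticSession(spec, rip, frames, audio_rip, audio_ema, annotations, truth)


def speech_session(
    n_cycles: int = 4,
    inhale_dur_s: float = 0.6,
    exhale_dur_s: float = 3.4,
    amplitude: float = 1.0,
    first_onset_s: float = 1.0,
    seed: int = 0,
    **overrides,
) -> SessionSpec:
    """Convenience spec: ``n_cycles`` abutting speech-breathing cycles.

    Consecutive cycles abut (each exhalation offset is the next inhalation
    onset), the pattern the trigger-plus-target sentence design enforces.
    """
    if n_cycles < 1:
        raise SpecError("n_cycles must be >= 1")
    cycles = []
    onset = first_onset_s
    for _ in range(n_cycles):
        cycles.append(CycleSpec(onset, inhale_dur_s, exhale_dur_s, amplitude))
        onset += inhale_dur_s + exhale_dur_s
    return SessionSpec(cycles=tuple(cycles), seed=seed, **overrides)


def tidal_session(
    n_cycles: int = 5,
    period_s: float = 4.0,
    amplitude: float = 0.3,
    seed: int = 0,
    **overrides,
) -> SyntheticSession:
    """Generate a tidal-breathing session: symmetric, lower-amplitude,
    nearly periodic cycles with no utterance annotations."""
    if period_s <= 0:
        raise SpecError("period_s must be positive")
    half = period_s / 2.0
    cycles = tuple(
        CycleSpec(0.5 + k * period_s, half, half, amplitude) for k in range(n_cycles)
    )
    spec = SessionSpec(cycles=cycles, annotate=False, seed=seed, **overrides)
    return generate_session(spec)
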