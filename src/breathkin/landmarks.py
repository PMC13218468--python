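"""Automatic breathing-landmark detection.

For each utterance, three landmarks of the speech-breathing cycle are
located on the filtered breathing signal (RIP or an EMA distance channel):

1. **inhalation onset** — the velocity zero crossing to the left of the
   inhalation velocity peak (the trough before the breath);
2. **inhalation offset / exhalation onset** — the first signal maximum to
   the right of the velocity peak (first downward velocity crossing);
3. **exhalation offset** — the signal minimum in a window from the velocity
   peak to the acoustic offset of the utterance plus a tail extension.

The velocity peak itself is the maximum of the velocity profile within a
window (default 2 s, centered) around the acoustic onset of the
utterance-initial word.

Zero crossings are evaluated against a small velocity floor (default 10 %
of the window-peak velocity) rather than exactly zero.  After Gaussian
filtering with sigma = 5 samples, a mathematically strict zero crossing at a
smooth onset is displaced by up to the truncated kernel half-width (4 sigma,
i.e. 200 ms at 100 Hz) because the filter leaks a strictly positive velocity
into the flat baseline; a floor proportional to the local peak velocity
cancels that leak to within ~1 sample (see docs/methods.md for the
calculation).  Setting ``zero_frac = 0`` recovers the strict rule.

All decisions are sample-resolution and deterministic: argmax/argmin ties
break to the earliest sample, and plateaus of the velocity floor take the
first sample of the plateau.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .core import TimeSeries
from .errors import DegenerateInputError, LandmarkValidationError

log = logging.getLogger(__name__)

__all__ = [
    "BreathingLandmarks",
    "DetectionConfig",
    "velocity_profile",
    "detect_landmarks",
    "apply_corrections",
    "UtteranceRecord",
    "ScreeningResult",
    "screen_utterances",
]

NO_INHALATION = "no_inhalation"
MANUALLY_CORRECTED = "manually_corrected"


@dataclass(frozen=True)
class BreathingLandmarks:
    """The three per-cycle events plus the velocity-peak time and QC flags.

    Times are in seconds on the signal's time base; undefined times (when
    ``no_inhalation`` is flagged) are NaN.
    """

    inhalation_onset_s: float
    inhalation_offset_s: float
    exhalation_offset_s: float
    velocity_peak_s: float
    qc_flags: frozenset[str] = frozenset()

    @property
    def flagged(self) -> bool:
        return NO_INHALATION in self.qc_flags

    def ordered(self) -> bool:
        return (
            self.inhalation_onset_s < self.inhalation_offset_s < self.exhalation_offset_s
        )


@dataclass(frozen=True)
class DetectionConfig:
    """Detection parameters.

    peak_window_s : width of the velocity-peak search window, centered on
        the acoustic onset (default 2 s, i.e. +-1 s)
    tail_extension_s : seconds appended after the acoustic offset for the
        exhalation-offset search (default 4 s)
    min_velocity_peak : QC threshold for the velocity peak in signal
        units/s; ``None`` means 5 % of the signal's inter-quartile range per
        second.  A window whose peak velocity falls below it yields the
        ``no_inhalation`` flag.
    zero_frac : velocity floor for "zero" crossings, as a fraction of the
        window-peak velocity (default 0.1; 0 = strict zero crossing)
    """

    peak_window_s: float = 2.0
    tail_extension_s: float = 4.0
    min_velocity_peak: float | None = None
    zero_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.peak_window_s <= 0 or self.tail_extension_s < 0:
            raise ValueError("windows must be positive")
        if not (0 <= self.zero_frac < 1):
            raise ValueError("zero_frac must lie in [0, 1)")


def velocity_profile(ts: TimeSeries) -> TimeSeries:
    """First time-derivative in units/s (central differences, one-sided at
    the edges); same length and time base as the input."""
    if len(ts) < 3:
        raise DegenerateInputError("velocity profile needs at least 3 samples")
    v = np.gradient(ts.values, ts.dt)
    return ts.with_values(v, units=f"{ts.units}/s")


def _default_min_velocity(ts: TimeSeries) -> float:
    q75, q25 = np.percentile(ts.values, [75, 25])
    return 0.05 * float(q75 - q25)  # per second


def detect_landmarks(
    ts: TimeSeries,
    acoustic_onset_s: float,
    acoustic_offset_s: float,
    cfg: DetectionConfig | None = None,
) -> BreathingLandmarks:
    """Locate the three breathing landmarks around one utterance.

    ``ts`` must already be conditioned (normalized, resampled, filtered).
    The acoustic onset must lie within the signal support; the search
    windows are clipped to the support.
    """
    cfg = cfg or DetectionConfig()
    if not (ts.start_s <= acoustic_onset_s <= ts.end_s):
        raise DegenerateInputError(
            f"acoustic onset {acoustic_onset_s} s outside signal support"
        )
    v = velocity_profile(ts).values
    n = len(ts)

    half = cfg.peak_window_s / 2.0
    w0 = ts.index_at(acoustic_onset_s - half, clip=True)
    w1 = ts.index_at(acoustic_onset_s + half, clip=True)
    peak_rel = int(np.argmax(v[w0 : w1 + 1]))  # ties -> earliest
    peak = w0 + peak_rel
    vmax = float(v[peak])

    min_peak = cfg.min_velocity_peak
    if min_peak is None:
        min_peak = _default_min_velocity(ts)
    if vmax <= max(min_peak, 0.0):
        return BreathingLandmarks(
            math.nan, math.nan, math.nan, ts.time_at(peak),
            qc_flags=frozenset({NO_INHALATION}),
        )

    floor = cfg.zero_frac * vmax

    # inhalation onset: last sample at/left of the peak with velocity <= floor
    onset_idx = None
    for i in range(peak, -1, -1):
        if v[i] <= floor:
            onset_idx = i
            break
    if onset_idx is None:
        onset_idx = w0
        log.warning(
            "%s: velocity never returns to the floor left of the peak; "
            "using the search-window start", ts.label,
        )

    # inhalation offset: first sample right of the peak with velocity <= floor
    off_idx = None
    for i in range(peak + 1, n):
        if v[i] <= floor:
            off_idx = i
            break
    if off_idx is None:
        off_idx = n - 1
        log.warning("%s: no downward velocity crossing after the peak; "
                    "using the signal end", ts.label)

    # exhalation offset: signal minimum from the velocity peak to the
    # acoustic offset + tail extension (clipped to the signal end)
    e1 = ts.index_at(acoustic_offset_s + cfg.tail_extension_s, clip=True)
    e0 = min(peak + 1, n - 1)
    if e1 < e0:
        e1 = e0
    exh_idx = e0 + int(np.argmin(ts.values[e0 : e1 + 1]))  # ties -> earliest

    return BreathingLandmarks(
        inhalation_onset_s=ts.time_at(onset_idx),
        inhalation_offset_s=ts.time_at(off_idx),
        exhalation_offset_s=ts.time_at(exh_idx),
        velocity_peak_s=ts.time_at(peak),
    )


def apply_corrections(
    lm: BreathingLandmarks, overrides: Mapping[str, float]
) -> BreathingLandmarks:
    """Replace landmark times with manual overrides.

    Empty overrides return the input unchanged (no flag).  Overrides that
    violate onset < offset < exhalation-offset raise
    :class:`LandmarkValidationError`.
    """
    allowed = {"inhalation_onset_s", "inhalation_offset_s",
               "exhalation_offset_s", "velocity_peak_s"}
    unknown = set(overrides) - allowed
    if unknown:
        raise LandmarkValidationError(f"unknown landmark fields: {sorted(unknown)}")
    if not overrides:
        return lm
    new = replace(
        lm,
        **{k: float(v) for k, v in overrides.items()},
        qc_flags=(lm.qc_flags - {NO_INHALATION}) | {MANUALLY_CORRECTED},
    )
    if not new.ordered():
        raise LandmarkValidationError(
            "corrected landmarks violate onset < offset < exhalation offset: "
            f"{new.inhalation_onset_s}, {new.inhalation_offset_s}, "
            f"{new.exhalation_offset_s}"
        )
    return new


# ---------------------------------------------------------------------------
# utterance screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtteranceRecord:
    """Landmarks for one utterance across all analysis channels."""

    utterance_id: str
    speaker: str
    sentence_type: str
    repetition: int
    landmarks: Mapping[str, BreathingLandmarks] = field(hash=False)


@dataclass
class ScreeningResult:
    kept: list[UtteranceRecord]
    excluded: list[tuple[UtteranceRecord, str]]
    removed_speakers: list[str]
    n_recorded: int

    @property
    def n_after_speaker_removal(self) -> int:
        return self.n_recorded - sum(
            1 for u, r in self.excluded if r == "speaker_removed"
        )

    @property
    def n_excluded_utterances(self) -> int:
        return sum(1 for u, r in self.excluded if r == NO_INHALATION)

    @property
    def exclusion_fraction(self) -> float:
        denom = self.n_after_speaker_removal
        return self.n_excluded_utterances / denom if denom else 0.0

    def kept_by_sentence_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for u in self.kept:
            out[u.sentence_type] = out.get(u.sentence_type, 0) + 1
        return out


def screen_utterances(
    utterances: Iterable[UtteranceRecord],
    reference_channel: str = "rip",
) -> ScreeningResult:
    """Exclude utterances lacking a pre-target inhalation.

    Speakers whose *every* utterance lacks an inhalation on the reference
    channel did not produce the expected breathing pattern at all and are
    removed entirely; among the remaining recordings, any utterance whose
    reference channel carries the ``no_inhalation`` flag is excluded, and
    the exclusion fraction is reported against the post-removal count.
    """
    utterances = list(utterances)
    by_speaker: dict[str, list[UtteranceRecord]] = {}
    for u in utterances:
        if reference_channel not in u.landmarks:
            raise KeyError(
                f"utterance {u.utterance_id!r} has no {reference_channel!r} channel"
            )
        by_speaker.setdefault(u.speaker, []).append(u)

    removed_speakers = sorted(
        spk for spk, items in by_speaker.items()
        if all(it.landmarks[reference_channel].flagged for it in items)
    )

    kept: list[UtteranceRecord] = []
    excluded: list[tuple[UtteranceRecord, str]] = []
    for u in utterances:
        if u.speaker in removed_speakers:
            excluded.append((u, "speaker_removed"))
        elif u.landmarks[reference_channel].flagged:
            excluded.append((u, NO_INHALATION))
        else:
            kept.append(u)

    result = ScreeningResult(kept, excluded, removed_speakers, len(utterances))
    log.info(
        "screening: %d recorded, %d speakers removed, %d/%d utterances excluded (%.1f%%)",
        result.n_recorded, len(removed_speakers), result.n_excluded_utterances,
        result.n_after_speaker_removal, 100 * result.exclusion_fraction,
    )
    return result
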