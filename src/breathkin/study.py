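"""Emulation of the sentence-production study design.

The recorded study crossed 4 target sentence types (short/long x
simple/complex) with 2 repetitions in 18 speakers: 144 utterances.  Each
target sentence was preceded by a fixed trigger sentence so that a fresh
breathing cycle — a rapid inhalation, then the target produced on the
exhalation — began before the target.  Two speakers never produced that
pattern and are removed entirely; of the remaining 128 utterances, 14 lack
a pre-target inhalation and are excluded (10.9 %), leaving 114 analyzed
utterances (28/27/30/29 per sentence type).

This module generates a synthetic cohort with exactly that design: one
short session per utterance, containing the trigger-sentence cycle followed
(for breathed utterances) by the target cycle, with the acoustic onset of
the target placed a known lag after the target inhalation onset.
Un-breathed utterances place the target acoustics mid-exhalation of the
trigger cycle, so the detector must *discover* the missing inhalation; the
exclusion bookkeeping is never hard-coded downstream.

Per-type cycle durations follow the observed medians (inhalations around
0.58-0.64 s; exhalations growing from about 3.3 s for short-simple to about
5.5 s for long-complex sentences); speaker and repetition variability is
log-normal around those medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Interval, IntervalTier
from .synthetic import CycleSpec, SessionSpec, SyntheticSession, generate_session

__all__ = [
    "SENTENCE_TYPES",
    "TYPE_PROFILES",
    "DEFAULT_EXCLUSION_PLAN",
    "CohortUtterance",
    "make_utterance_session",
    "generate_cohort",
]

SENTENCE_TYPES = ("short_simple", "short_complex", "long_simple", "long_complex")

#: per sentence type: (median inhalation s, median exhalation s, latent amplitude)
TYPE_PROFILES: dict[str, tuple[float, float, float]] = {
    "short_simple": (0.58, 3.3, 1.00),
    "short_complex": (0.63, 3.8, 1.00),
    "long_simple": (0.64, 4.9, 0.95),
    "long_complex": (0.59, 5.5, 0.90),
}

#: the study's screening outcome, used as the *design* of the synthetic
#: cohort (which recordings lack a pre-target inhalation); the analysis must
#: rediscover it from the signals.  Two speakers never inhale before
#: targets; 4/5/2/3 further utterances per sentence type lack the
#: inhalation, leaving 28/27/30/29 analyzed utterances.
DEFAULT_EXCLUSION_PLAN: dict[str, object] = {
    "removed_speakers": ("P17", "P18"),
    "no_inhalation": (
        ("P01", "short_simple", 1), ("P03", "short_simple", 2),
        ("P05", "short_simple", 1), ("P09", "short_simple", 2),
        ("P02", "short_complex", 1), ("P04", "short_complex", 2),
        ("P07", "short_complex", 1), ("P11", "short_complex", 2),
        ("P13", "short_complex", 1),
        ("P06", "long_simple", 2), ("P10", "long_simple", 1),
        ("P08", "long_complex", 1), ("P12", "long_complex", 2),
        ("P15", "long_complex", 1),
    ),
}


@dataclass
class CohortUtterance:
    """One recorded utterance: metadata plus its synthetic session."""

    speaker: str
    sentence_type: str
    repetition: int
    session: SyntheticSession
    has_inhalation: bool

    @property
    def utterance_id(self) -> str:
        return f"{self.speaker}_{self.sentence_type}_r{self.repetition}"


_TRIGGER = CycleSpec(onset_s=0.6, inhale_dur_s=0.5, exhale_dur_s=2.6, amplitude=0.9)


def make_utterance_session(
    speaker: str,
    sentence_type: str,
    repetition: int,
    seed: int,
    has_inhalation: bool = True,
    inhale_scale: float = 1.0,
    exhale_scale: float = 1.0,
    sonja_lag_s: float = 0.5,
    rip_noise_sd: float = 0.02,
    sensor_noise_sd: float = 0.15,
    drift_per_s: float = 0.05,
    sync_offset_s: float = 0.35,
    rip_rate_hz: float = 44100.0,
    ema_rate_hz: float = 1250.0,
) -> SyntheticSession:
    """One trigger-plus-target recording.

    A breathed utterance has the target cycle abutting the trigger
    exhalation; an un-breathed one stretches the trigger exhalation instead
    and places the target acoustics inside it.
    """
    inh, exh, amp = TYPE_PROFILES[sentence_type]
    inh *= inhale_scale
    exh *= exhale_scale
    if has_inhalation:
        target = CycleSpec(_TRIGGER.end_s, inh, exh, amp)
        # speakers resume breathing after the target; the recovery breath is
        # long enough that the exhalation-offset search window (acoustic
        # offset + tail extension) ends inside it, keeping the target trough
        # the unique minimum instead of bordering a flat signal tail
        recovery = CycleSpec(target.end_s, 0.4, 4.0, 0.6)
        cycles = (_TRIGGER, target, recovery)
        acoustic_on = target.onset_s + sonja_lag_s
        acoustic_off = target.end_s - 0.05 * target.exhale_dur_s
    else:
        # same overall span, but the speaker carries on exhaling through the
        # point where the target inhalation should have occurred
        stretched = CycleSpec(_TRIGGER.onset_s, _TRIGGER.inhale_dur_s,
                              _TRIGGER.exhale_dur_s + inh + exh,
                              _TRIGGER.amplitude)
        recovery = CycleSpec(stretched.end_s, 0.4, 4.0, 0.6)
        cycles = (stretched, recovery)
        acoustic_on = _TRIGGER.end_s + sonja_lag_s
        acoustic_off = stretched.end_s - 0.2
    spec = SessionSpec(
        cycles=cycles,
        rip_noise_sd=rip_noise_sd,
        sensor_noise_sd=sensor_noise_sd,
        drift_per_s=drift_per_s,
        sync_offset_s=sync_offset_s,
        sonja_lag_s=sonja_lag_s,
        rip_rate_hz=rip_rate_hz,
        ema_rate_hz=ema_rate_hz,
        annotate=False,
        seed=seed,
    )
    session = generate_session(spec)
    session.annotations = IntervalTier(
        "sentence", [Interval(acoustic_on, acoustic_off, "Sonja")]
    )
    if not has_inhalation:
        session.truth = []  # no target cycle: nothing to recover
    else:
        session.truth = session.truth[1:2]  # keep only the target cycle
    return session


def generate_cohort(
    seed: int = 0,
    n_speakers: int = 18,
    n_repetitions: int = 2,
    exclusion_plan: dict | None = None,
    rip_rate_hz: float = 44100.0,
    ema_rate_hz: float = 1250.0,
    **session_kwargs,
) -> list[CohortUtterance]:
    """Generate the full synthetic cohort (default 4 x 2 x 18 = 144
    utterances) with the study's screening outcome built into the design."""
    plan = DEFAULT_EXCLUSION_PLAN if exclusion_plan is None else exclusion_plan
    removed = set(plan["removed_speakers"])
    unbreathed = set(plan["no_inhalation"])
    rng = np.random.default_rng(seed)
    cohort: list[CohortUtterance] = []
    speakers = [f"P{i + 1:02d}" for i in range(n_speakers)]
    speaker_scale = {s: float(np.exp(rng.normal(0.0, 0.08))) for s in speakers}
    # utterance-level dispersion calibrated to the observed summary spreads:
    # phase-duration IQRs around +-15 % and acoustic-lag IQRs around +-20 %.
    # Inhalation and exhalation jitter independently so the cycle *shape*
    # (and with it the z-scored amplitude) varies between utterances.
    for speaker in speakers:
        for stype in SENTENCE_TYPES:
            for rep in range(1, n_repetitions + 1):
                has_inh = speaker not in removed and (speaker, stype, rep) not in unbreathed
                j_inh = float(np.exp(rng.normal(0.0, 0.12)))
                j_exh = float(np.exp(rng.normal(0.0, 0.10)))
                lag = float(np.clip(0.5 + rng.normal(0.0, 0.09), 0.25, 0.9))
                sess_seed = int(rng.integers(0, 2**31 - 1))
                session = make_utterance_session(
                    speaker, stype, rep,
                    seed=sess_seed,
                    has_inhalation=has_inh,
                    inhale_scale=speaker_scale[speaker] * j_inh,
                    exhale_scale=speaker_scale[speaker] * j_exh,
                    sonja_lag_s=lag,
                    rip_rate_hz=rip_rate_hz,
                    ema_rate_hz=ema_rate_hz,
                    **session_kwargs,
                )
                cohort.append(CohortUtterance(speaker, stype, rep, session, has_inh))
    return cohort
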