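"""End-to-end orchestration: simulate/load -> synchronize -> condition ->
distances -> landmarks -> screening -> parameters -> comparisons.

The session-level entry point is :func:`analyze_session`, which turns one
recording (RIP channel, EMA sensor frames, two sync audio tracks, acoustic
segmentation) into aligned 100 Hz analysis channels and per-utterance
landmarks.  Cohort-level helpers aggregate parameters, summary tables,
Jensen-Shannon distances, correlation posteriors and cross-correlations,
and :func:`run_pipeline` drives the whole chain from a single config with
one root seed, writing CSV/JSON artifacts plus a checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import McmcConfig, REDUCED_MCMC, fit_gp_trajectory_model, fit_pairwise_correlation
from .core import TimeSeries
from .cycles import cycle_parameters, distribution_distance, summarize_by_group, summary_table
from .distances import all_distances
from .errors import ConfigurationError
from .io_formats import write_cycle_report, write_textgrid, write_timeseries_table, write_wav
from .landmarks import (BreathingLandmarks, DetectionConfig, UtteranceRecord,
                        detect_landmarks, screen_utterances)
from .preprocess import (PreprocessConfig, detect_sync_impulse, gaussian_smooth,
                         normalize_amplitude, preprocess, resample)
from .study import CohortUtterance, generate_cohort
from .synthetic import SyntheticSession
from .trajectories import extract_cycle_window, max_cross_correlation, resample_to_steps

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SessionAnalysis",
    "analyze_session",
    "utterance_record",
    "analyze_cohort",
    "CohortAnalysis",
    "run_pipeline",
    "save_session",
]

PARAMETERS = ("inhalation_duration_ms", "exhalation_duration_ms",
              "delta_sonja_ms", "inhalation_amplitude_sd")
RIP_CHANNEL = "rip"


@dataclass
class SessionAnalysis:
    """Aligned analysis channels and acoustic intervals for one session.

    All channels are at the analysis rate with the clapperboard impulse at
    t = 0; ``channels`` holds the RIP channel plus the six EMA distance
    channels, max-abs normalized and Gaussian filtered.
    """

    channels: dict[str, TimeSeries]
    intervals: list  # aligned acoustic intervals, one per utterance
    clap_rip_s: float
    clap_ema_s: float


def analyze_session(
    session: SyntheticSession,
    pre_cfg: PreprocessConfig | None = None,
) -> SessionAnalysis:
    """Synchronize and condition one session into analysis channels.

    The clapperboard impulse is located in each system's audio track; every
    stream is then re-timed so the clap is t = 0.  The RIP channel is
    normalized, resampled and filtered; EMA coordinates are resampled and
    filtered in mm, the distance measures computed, and each distance
    channel normalized to match the RIP scale.
    """
    cfg = pre_cfg or PreprocessConfig()
    clap_rip = detect_sync_impulse(session.audio_rip, cfg.sync_threshold_frac,
                                   cfg.sync_window_s)
    clap_ema = detect_sync_impulse(session.audio_ema, cfg.sync_threshold_frac,
                                   cfg.sync_window_s)

    channels: dict[str, TimeSeries] = {}
    channels[RIP_CHANNEL] = preprocess(session.rip, cfg).shifted(-clap_rip)

    smoothed = {
        role: {
            dim: gaussian_smooth(resample(ts, cfg.target_rate_hz),
                                 cfg.gaussian_sigma_samples)
            for dim, ts in dims.items()
        }
        for role, dims in session.sensors.sensors.items()
    }
    frames = type(session.sensors)(smoothed)
    for dist in all_distances(frames):
        channels[dist.channel] = normalize_amplitude(dist.series).shifted(-clap_ema)

    intervals = session.annotations.shifted(-clap_rip).intervals
    return SessionAnalysis(channels, intervals, clap_rip, clap_ema)


def utterance_record(
    analysis: SessionAnalysis,
    interval,
    utterance_id: str,
    speaker: str,
    sentence_type: str,
    repetition: int,
    det_cfg: DetectionConfig | None = None,
) -> UtteranceRecord:
    """Detect landmarks on every channel for one acoustic interval."""
    det = det_cfg or DetectionConfig()
    lms: dict[str, BreathingLandmarks] = {}
    for name, ts in analysis.channels.items():
        lms[name] = detect_landmarks(ts, interval.start_s, interval.end_s, det)
    return UtteranceRecord(utterance_id, speaker, sentence_type, repetition, lms)


@dataclass
class CohortAnalysis:
    screening: object
    records: list[UtteranceRecord]
    parameters: pd.DataFrame           # long: one row per utterance x channel
    acoustic_onsets: dict[str, float]  # utterance_id -> aligned onset (s)
    analyses: dict[str, SessionAnalysis] = field(default_factory=dict)


def analyze_cohort(
    cohort: list[CohortUtterance],
    pre_cfg: PreprocessConfig | None = None,
    det_cfg: DetectionConfig | None = None,
    keep_analyses: bool = False,
) -> CohortAnalysis:
    """Run synchronization, detection, screening and parameter extraction
    over a full cohort of single-utterance sessions."""
    records: list[UtteranceRecord] = []
    analyses: dict[str, SessionAnalysis] = {}
    onsets: dict[str, float] = {}
    for utt in cohort:
        ana = analyze_session(utt.session, pre_cfg)
        iv = ana.intervals[0]
        rec = utterance_record(ana, iv, utt.utterance_id, utt.speaker,
                               utt.sentence_type, utt.repetition, det_cfg)
        records.append(rec)
        onsets[utt.utterance_id] = iv.start_s
        if keep_analyses:
            analyses[utt.utterance_id] = ana

    screening = screen_utterances(records, reference_channel=RIP_CHANNEL)

    rows: list[dict] = []
    ana_by_id = analyses if keep_analyses else None
    for utt in cohort:
        rec = next(r for r in screening.kept if r.utterance_id == utt.utterance_id) \
            if any(r.utterance_id == utt.utterance_id for r in screening.kept) else None
        if rec is None:
            continue
        ana = analyses.get(utt.utterance_id) if ana_by_id else analyze_session(
            utt.session, pre_cfg)
        onset = onsets[utt.utterance_id]
        for name, ts in ana.channels.items():
            lm = rec.landmarks[name]
            if lm.flagged:
                continue
            try:
                p = cycle_parameters(ts, lm, onset)
            except Exception as exc:  # zero-variance or truncated cycle
                log.warning("%s/%s: parameters skipped (%s)",
                            utt.utterance_id, name, exc)
                continue
            rows.append({
                "utterance_id": utt.utterance_id,
                "speaker": utt.speaker,
                "sentence_type": utt.sentence_type,
                "repetition": utt.repetition,
                "dimension": name,
                "inhalation_duration_ms": p.inhalation_duration_ms,
                "exhalation_duration_ms": p.exhalation_duration_ms,
                "delta_sonja_ms": p.delta_sonja_ms,
                "inhalation_amplitude_sd": p.inhalation_amplitude_sd,
            })
    params = pd.DataFrame(rows)
    return CohortAnalysis(screening, records, params, onsets,
                          analyses if keep_analyses else {})


# ---------------------------------------------------------------------------
# cohort-level comparison tables
# ---------------------------------------------------------------------------

def paired_parameter_vectors(
    params: pd.DataFrame, channel: str, parameter: str, sentence_type: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """RIP vs EMA-channel values of one parameter, paired by utterance."""
    df = params
    if sentence_type is not None:
        df = df[df["sentence_type"] == sentence_type]
    rip = df[df["dimension"] == RIP_CHANNEL].set_index("utterance_id")[parameter]
    ema = df[df["dimension"] == channel].set_index("utterance_id")[parameter]
    common = rip.index.intersection(ema.index)
    return rip.loc[common].to_numpy(), ema.loc[common].to_numpy()


def correlation_table(
    params: pd.DataFrame,
    mcmc: McmcConfig,
    parameters: tuple[str, ...] = PARAMETERS,
    channels: tuple[str, ...] | None = None,
    by_sentence_type: bool = True,
) -> pd.DataFrame:
    """Posterior correlation of each EMA channel with RIP per parameter
    (and sentence type), in the layout of the study's correlation tables."""
    chans = channels or tuple(
        c for c in params["dimension"].unique() if c != RIP_CHANNEL)
    stypes = sorted(params["sentence_type"].unique()) if by_sentence_type else [None]
    rows = []
    for parameter in parameters:
        for channel in chans:
            for stype in stypes:
                x, y = paired_parameter_vectors(params, channel, parameter, stype)
                if len(x) < 5:
                    continue
                post = fit_pairwise_correlation(x, y, mcmc=mcmc)
                rows.append({
                    "parameter": parameter,
                    "dimension": channel,
                    "sentence_type": stype or "all",
                    "n": len(x),
                    "rho_mean": post.rho_mean,
                    "hdi_low": post.hdi_low,
                    "hdi_high": post.hdi_high,
                    "pr_gt_zero": post.pr_gt_zero,
                    "rhat_max": post.diagnostics[1],
                })
    return pd.DataFrame(rows)


def js_distance_table(params: pd.DataFrame,
                      parameters: tuple[str, ...] = PARAMETERS) -> pd.DataFrame:
    """Jensen-Shannon distance of each EMA channel's parameter distribution
    from the RIP distribution, per sentence type."""
    rows = []
    chans = [c for c in params["dimension"].unique() if c != RIP_CHANNEL]
    for parameter in parameters:
        for stype in sorted(params["sentence_type"].unique()):
            sel = params[params["sentence_type"] == stype]
            rip_vals = sel[sel["dimension"] == RIP_CHANNEL][parameter].to_numpy()
            for channel in chans:
                ema_vals = sel[sel["dimension"] == channel][parameter].to_numpy()
                if len(rip_vals) == 0 or len(ema_vals) == 0:
                    continue
                rows.append({
                    "parameter": parameter,
                    "dimension": channel,
                    "sentence_type": stype,
                    "js_distance": distribution_distance(rip_vals, ema_vals),
                })
    return pd.DataFrame(rows)


def cross_correlation_table(
    cohort: list[CohortUtterance],
    analysis: CohortAnalysis,
    pad_s: float = 1.5,
    max_lag_s: float = 0.5,
) -> pd.DataFrame:
    """Whole-trajectory similarity of each EMA channel with RIP per kept
    utterance: maximum normalized cross-correlation within +-max_lag_s."""
    kept_ids = {r.utterance_id for r in analysis.screening.kept}
    rows = []
    for utt in cohort:
        if utt.utterance_id not in kept_ids:
            continue
        ana = analysis.analyses.get(utt.utterance_id)
        if ana is None:
            ana = analyze_session(utt.session)
        rec = next(r for r in analysis.screening.kept
                   if r.utterance_id == utt.utterance_id)
        rip_lm = rec.landmarks[RIP_CHANNEL]
        rip_win = extract_cycle_window(ana.channels[RIP_CHANNEL], rip_lm, pad_s)
        for name, ts in ana.channels.items():
            if name == RIP_CHANNEL:
                continue
            win = extract_cycle_window(ts, rip_lm, pad_s)
            r, lag = max_cross_correlation(rip_win, win, max_lag_s)
            rows.append({
                "utterance_id": utt.utterance_id,
                "speaker": utt.speaker,
                "sentence_type": utt.sentence_type,
                "dimension": name,
                "coefficient": r,
                "lag_s": lag,
            })
    return pd.DataFrame(rows)


def cycle_trajectories(
    cohort: list[CohortUtterance],
    analysis: CohortAnalysis,
    channel: str,
    sentence_type: str | None = None,
    n_steps: int = 50,
    pad_s: float = 1.5,
) -> list:
    """Z-scored, 50-step cycle trajectories of one channel over kept
    utterances, windowed by the RIP landmarks (shared reference)."""
    out = []
    kept = {r.utterance_id: r for r in analysis.screening.kept}
    for utt in cohort:
        rec = kept.get(utt.utterance_id)
        if rec is None or (sentence_type and utt.sentence_type != sentence_type):
            continue
        ana = analysis.analyses.get(utt.utterance_id) or analyze_session(utt.session)
        win = extract_cycle_window(ana.channels[channel],
                                   rec.landmarks[RIP_CHANNEL], pad_s)
        vals = win.values
        sd = vals.std(ddof=1)
        if sd == 0:
            continue
        zwin = win.with_values((vals - vals.mean()) / sd)
        out.append(resample_to_steps(zwin, n_steps, channel=channel,
                                     utterance_id=utt.utterance_id,
                                     speaker=utt.speaker))
    return out


# ---------------------------------------------------------------------------
# run config, artifact writing
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One pipeline run: exactly one of ``simulate`` (cohort generation
    kwargs) or ``input_dir`` must be given; every random choice flows from
    ``seed``."""

    out_dir: str
    simulate: dict | None = None
    input_dir: str | None = None
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    mcmc: McmcConfig = field(default_factory=lambda: REDUCED_MCMC)
    run_correlations: bool = True
    run_gp: bool = False
    gp_channel: str = "chestmid_x"
    gp_sentence_type: str = "short_complex"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ConfigurationError(
                "exactly one of {simulate, input_dir} must be configured")


@dataclass
class RecordedSession:
    """A session re-read from disk (duck-typed like SyntheticSession for
    analysis; carries no generator spec or ground truth)."""

    rip: TimeSeries
    sensors: object
    audio_rip: TimeSeries
    audio_ema: TimeSeries
    annotations: object


def load_session(in_dir: str) -> tuple[RecordedSession, dict]:
    """Read one session from the layout written by :func:`save_session`."""
    from .distances import SensorFrameSet
    from .io_formats import read_textgrid, read_timeseries_table, read_wav

    rip = read_timeseries_table(os.path.join(in_dir, "rip.tsv"))[0]
    ema = read_timeseries_table(os.path.join(in_dir, "ema.tsv"))
    frames = SensorFrameSet.from_mapping({ts.label: ts for ts in ema})
    audio_rip = read_wav(os.path.join(in_dir, "audio_rip.wav"), label="audio_rip")
    audio_ema = read_wav(os.path.join(in_dir, "audio_ema.wav"), label="audio_ema")
    tiers = read_textgrid(os.path.join(in_dir, "annotations.TextGrid"))
    annotations = tiers[0]
    annotations.intervals = annotations.labelled()  # drop gap-filler intervals
    meta_path = os.path.join(in_dir, "meta.json")
    meta = {}
    if os.path.exists(meta_path):
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    session = RecordedSession(rip, frames, audio_rip, audio_ema, annotations)
    return session, meta


def load_cohort(input_dir: str) -> list[CohortUtterance]:
    """Read every session subdirectory of ``input_dir`` as a cohort."""
    cohort: list[CohortUtterance] = []
    for name in sorted(os.listdir(input_dir)):
        sub = os.path.join(input_dir, name)
        if not os.path.isdir(sub) or not os.path.exists(os.path.join(sub, "rip.tsv")):
            continue
        session, meta = load_session(sub)
        cohort.append(CohortUtterance(
            speaker=str(meta.get("speaker", name)),
            sentence_type=str(meta.get("sentence_type", "unknown")),
            repetition=int(meta.get("repetition", 1)),
            session=session,  # type: ignore[arg-type]
            has_inhalation=bool(meta.get("has_inhalation", True)),
        ))
    if not cohort:
        raise ConfigurationError(f"no session directories found under {input_dir}")
    return cohort


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_session(session: SyntheticSession, out_dir: str, meta: dict | None = None) -> None:
    """Write one session as portable text/WAV artifacts (tables, audio,
    TextGrid, truth CSV)."""
    os.makedirs(out_dir, exist_ok=True)
    write_timeseries_table(os.path.join(out_dir, "rip.tsv"), [session.rip])
    flat = [ts for dims in session.sensors.sensors.values() for ts in dims.values()]
    write_timeseries_table(os.path.join(out_dir, "ema.tsv"), flat)
    write_wav(os.path.join(out_dir, "audio_rip.wav"), session.audio_rip)
    write_wav(os.path.join(out_dir, "audio_ema.wav"), session.audio_ema)
    with open(os.path.join(out_dir, "annotations.TextGrid"), "w", encoding="utf-8") as fh:
        write_textgrid(fh, [session.annotations])
    truth = pd.DataFrame([
        {
            "inhalation_onset_s": lm.inhalation_onset_s,
            "inhalation_offset_s": lm.inhalation_offset_s,
            "exhalation_offset_s": lm.exhalation_offset_s,
            "velocity_peak_s": lm.velocity_peak_s,
        }
        for lm in session.truth
    ])
    truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    if meta:
        with open(os.path.join(out_dir, "meta.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis chain and write artifacts.

    Returns the manifest: stage log plus every written file with its SHA-256
    checksum.  Raises on stage failure after recording the stage name.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": [], "files": {},
                      "config": {
                          "preprocess": dataclasses.asdict(cfg.preprocess),
                          "detection": dataclasses.asdict(cfg.detection),
                          "mcmc": dataclasses.asdict(cfg.mcmc),
                      }}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(cfg.out_dir, name)
        df.to_csv(path, index=False)
        manifest["files"][name] = _sha256(path)

    stage = "simulate"
    try:
        if cfg.simulate is not None:
            cohort = generate_cohort(seed=cfg.seed, **cfg.simulate)
        else:
            stage = "load"
            cohort = load_cohort(cfg.input_dir)
        manifest["stages"].append({"stage": stage, "n_utterances": len(cohort)})

        stage = "detect"
        analysis = analyze_cohort(cohort, cfg.preprocess, cfg.detection,
                                  keep_analyses=True)
        scr = analysis.screening
        manifest["stages"].append({
            "stage": stage,
            "recorded": scr.n_recorded,
            "removed_speakers": scr.removed_speakers,
            "excluded": [(u.utterance_id, reason) for u, reason in scr.excluded],
            "exclusion_fraction": scr.exclusion_fraction,
            "kept": len(scr.kept),
        })

        lm_rows = [
            {
                "utterance_id": r.utterance_id, "speaker": r.speaker,
                "sentence_type": r.sentence_type, "repetition": r.repetition,
                "dimension": name,
                "inhalation_onset_s": lm.inhalation_onset_s,
                "inhalation_offset_s": lm.inhalation_offset_s,
                "exhalation_offset_s": lm.exhalation_offset_s,
                "velocity_peak_s": lm.velocity_peak_s,
                "qc_flags": "|".join(sorted(lm.qc_flags)),
            }
            for r in analysis.records for name, lm in sorted(r.landmarks.items())
        ]
        emit("landmarks.csv", pd.DataFrame(lm_rows))

        stage = "parameters"
        emit("parameters.csv", analysis.parameters)
        report = write_cycle_report(
            analysis.parameters.rename(columns={"dimension": "dimension"})
            .to_dict("records"))
        path = os.path.join(cfg.out_dir, "cycle_report.csv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(report)
        manifest["files"]["cycle_report.csv"] = _sha256(path)
        for parameter in PARAMETERS:
            rows = summarize_by_group(
                analysis.parameters[parameter],
                list(zip(analysis.parameters["dimension"],
                         analysis.parameters["sentence_type"])),
            )
            digits = 2 if parameter == "inhalation_amplitude_sd" else 0
            emit(f"summary_{parameter}.csv",
                 summary_table(rows, digits=digits).reset_index())

        stage = "similarity"
        emit("js_distances.csv", js_distance_table(analysis.parameters))
        xcorr = cross_correlation_table(cohort, analysis)
        emit("cross_correlation.csv", xcorr)
        xs = xcorr.groupby(["dimension", "sentence_type"])["coefficient"]
        emit("cross_correlation_summary.csv",
             xs.agg(median="median",
                    low=lambda s: s.quantile(0.25),
                    high=lambda s: s.quantile(0.75),
                    lo_range="min", hi_range="max").reset_index())

        if cfg.run_correlations:
            stage = "correlations"
            mc = dataclasses.replace(cfg.mcmc, seed=cfg.seed)
            emit("correlations.csv", correlation_table(analysis.parameters, mc))

        if cfg.run_gp:
            stage = "gp_contrast"
            mc = dataclasses.replace(cfg.mcmc, seed=cfg.seed)
            ta = cycle_trajectories(cohort, analysis, RIP_CHANNEL,
                                    cfg.gp_sentence_type)
            tb = cycle_trajectories(cohort, analysis, cfg.gp_channel,
                                    cfg.gp_sentence_type)
            contrast = fit_gp_trajectory_model(ta, tb, mcmc=mc)
            cpath = os.path.join(
                cfg.out_dir, f"contrast_{cfg.gp_sentence_type}_{cfg.gp_channel}.json")
            with open(cpath, "w", encoding="utf-8") as fh:
                json.dump({
                    "channels": list(contrast.channels),
                    "steps": contrast.steps.tolist(),
                    "mean_diff": contrast.mean_diff.tolist(),
                    "band_low": contrast.band_diff[0].tolist(),
                    "band_high": contrast.band_diff[1].tolist(),
                    "nonzero_ranges": contrast.nonzero_ranges,
                }, fh, indent=1)
            manifest["files"][os.path.basename(cpath)] = _sha256(cpath)
    except Exception as exc:
        manifest["stages"].append({"stage": stage, "error": str(exc)})
        mpath = os.path.join(cfg.out_dir, "manifest.json")
        with open(mpath, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        raise

    mpath = os.path.join(cfg.out_dir, "manifest.json")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("pipeline complete: %d artifacts in %s", len(manifest["files"]),
             cfg.out_dir)
    return manifest
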