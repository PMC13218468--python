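"""Per-cycle breathing parameters and their summary statistics.

Temporal parameters (ms): inhalation duration (onset -> offset), exhalation
duration (offset -> exhalation offset) and the acoustic-kinematic lag
Delta-Sonja (inhalation onset -> acoustic onset of the utterance-initial
word; positive when the acoustics follow the inhalation onset).

Spatial parameter: the inhalation amplitude in standard-deviation units —
the breathing cycle (inhalation onset to exhalation offset) is z-scored and
the amplitude is the rise of the standardized signal from inhalation onset
to inhalation offset.  Being unit-free, it is directly comparable between
the normalized RIP channel and mm-scaled EMA distances.

Summaries are medians with inter-quartile ranges; distribution similarity
uses the Jensen-Shannon distance (base-2, bounded in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .core import TimeSeries
from .errors import DegenerateInputError
from .landmarks import BreathingLandmarks

__all__ = [
    "CycleParameters",
    "SummaryRow",
    "temporal_parameters",
    "inhalation_amplitude",
    "cycle_parameters",
    "summarize_by_group",
    "summary_table",
    "distribution_distance",
]


@dataclass(frozen=True)
class CycleParameters:
    inhalation_duration_ms: float
    exhalation_duration_ms: float
    delta_sonja_ms: float
    inhalation_amplitude_sd: float

    def __post_init__(self) -> None:
        if self.inhalation_duration_ms <= 0 or self.exhalation_duration_ms <= 0:
            raise ValueError("cycle durations must be positive")
        if not np.isfinite(self.inhalation_amplitude_sd):
            raise ValueError("inhalation amplitude must be finite")


@dataclass(frozen=True)
class SummaryRow:
    dimension: str
    sentence_type: str
    n: int
    median: float
    iqr_low: float
    iqr_high: float

    def __post_init__(self) -> None:
        if not (self.iqr_low <= self.median <= self.iqr_high):
            raise ValueError("IQR bounds must bracket the median")


def temporal_parameters(
    lm: BreathingLandmarks, acoustic_onset_s: float
) -> tuple[float, float, float]:
    """(inhalation, exhalation, Delta-Sonja) durations in ms.

    The two phase durations telescope: they sum exactly to the breathing
    cycle (exhalation offset minus inhalation onset).  Raises on flagged
    landmarks, for which the parameters are undefined.
    """
    if lm.flagged:
        raise DegenerateInputError("temporal parameters undefined for flagged landmarks")
    inhal = (lm.inhalation_offset_s - lm.inhalation_onset_s) * 1000.0
    exhal = (lm.exhalation_offset_s - lm.inhalation_offset_s) * 1000.0
    delta = (acoustic_onset_s - lm.inhalation_onset_s) * 1000.0
    return inhal, exhal, delta


def inhalation_amplitude(ts: TimeSeries, lm: BreathingLandmarks) -> float:
    """Inhalation amplitude in SD units.

    Samples in [inhalation onset, exhalation offset] are z-scored (sample
    SD, ddof=1); the amplitude is z(inhalation offset) - z(inhalation
    onset).  Invariant under positive affine rescaling of the signal.
    """
    if lm.flagged:
        raise DegenerateInputError("amplitude undefined for flagged landmarks")
    cyc = ts.slice_time(lm.inhalation_onset_s, lm.exhalation_offset_s)
    if len(cyc) < 3:
        raise DegenerateInputError("cycle has fewer than 3 samples")
    sd = float(np.std(cyc.values, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("zero-variance cycle")
    z = (cyc.values - float(np.mean(cyc.values))) / sd
    i_on = cyc.index_at(lm.inhalation_onset_s, clip=True)
    i_off = cyc.index_at(lm.inhalation_offset_s, clip=True)
    return float(z[i_off] - z[i_on])


def cycle_parameters(
    ts: TimeSeries, lm: BreathingLandmarks, acoustic_onset_s: float
) -> CycleParameters:
    inhal, exhal, delta = temporal_parameters(lm, acoustic_onset_s)
    amp = inhalation_amplitude(ts, lm)
    return CycleParameters(inhal, exhal, delta, amp)


def summarize_by_group(
    values: Iterable[float],
    groups: Iterable[tuple[Hashable, ...]] | None = None,
    group_names: Sequence[str] = ("dimension", "sentence_type"),
) -> list[SummaryRow]:
    """Median and IQR (25th/75th percentiles) per group.

    ``groups`` carries one (dimension, sentence_type) key per value; when
    omitted all values form one group.  Empty inputs yield no rows.
    """
    vals = np.asarray(list(values), dtype=float)
    if groups is None:
        keys = [("all", "all")] * len(vals)
    else:
        keys = list(groups)
    if len(keys) != len(vals):
        raise ValueError("values and groups must have equal length")
    out: list[SummaryRow] = []
    seen: list[tuple[Hashable, ...]] = []
    for key in keys:
        if key not in seen:
            seen.append(key)
    for key in seen:
        sel = vals[[k == key for k in keys]]
        q25, med, q75 = np.percentile(sel, [25, 50, 75])
        out.append(SummaryRow(str(key[0]), str(key[1]), len(sel),
                              float(med), float(q25), float(q75)))
    return out


def summary_table(rows: Iterable[SummaryRow], digits: int = 0) -> pd.DataFrame:
    """Wide table: rows = dimension, columns = sentence type, cells
    formatted as ``median (iqr_low - iqr_high)``."""
    recs = list(rows)
    df = pd.DataFrame(
        {
            "dimension": [r.dimension for r in recs],
            "sentence_type": [r.sentence_type for r in recs],
            "cell": [
                f"{round(r.median, digits) if digits else int(round(r.median))} "
                f"({round(r.iqr_low, digits) if digits else int(round(r.iqr_low))} - "
                f"{round(r.iqr_high, digits) if digits else int(round(r.iqr_high))})"
                for r in recs
            ],
        }
    )
    return df.pivot(index="dimension", columns="sentence_type", values="cell")


def _fd_bins(pooled: np.ndarray, min_bins: int = 10, max_bins: int = 512) -> int:
    """Freedman-Diaconis bin count on the pooled sample, clipped to
    [min_bins, max_bins] (a near-zero IQR would otherwise explode it)."""
    n = len(pooled)
    iqr = float(np.subtract(*np.percentile(pooled, [75, 25])))
    span = float(pooled.max() - pooled.min())
    if iqr == 0.0 or span == 0.0:
        return min_bins
    width = 2.0 * iqr / n ** (1.0 / 3.0)
    return int(np.clip(np.ceil(span / width), min_bins, max_bins))


def distribution_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Jensen-Shannon distance between two sample distributions, in [0, 1].

    Both samples are histogrammed on a shared grid spanning the union of
    their ranges (Freedman-Diaconis bin count on the pooled sample, at
    least 10 bins); the distance is the square root of the base-2
    Jensen-Shannon divergence of the two probability vectors: 0 for
    identical samples, 1 for disjoint supports.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.size == 0 or bv.size == 0:
        raise DegenerateInputError("distribution_distance needs non-empty samples")
    pooled = np.concatenate([av, bv])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        hi = lo + 1.0  # all values identical -> both distributions coincide
    edges = np.linspace(lo, hi, _fd_bins(pooled) + 1)
    pa, _ = np.histogram(av, bins=edges)
    pb, _ = np.histogram(bv, bins=edges)
    d = float(jensenshannon(pa, pb, base=2))
    return 0.0 if np.isnan(d) else d
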