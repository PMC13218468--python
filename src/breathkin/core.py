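"""Core signal containers used throughout the pipeline.

Every 1-D signal in the analysis — the thoracic RIP band trace, raw EMA
coordinate trajectories, derived distance measures, velocity profiles and the
synchronization audio — is carried as a :class:`TimeSeries`: a uniformly
sampled value array with a sampling rate and a start time in seconds.
Acoustic segmentations (Praat interval tiers) are carried as
:class:`IntervalTier`.

Time convention: seconds, zero-based at recording start; intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .errors import DegenerateInputError

__all__ = ["TimeSeries", "Interval", "IntervalTier"]


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled 1-D signal.

    Parameters
    ----------
    values : array-like of float
        Sample values; must be finite and non-empty.
    rate_hz : float
        Sampling rate in Hz, strictly positive.
    start_s : float
        Time of the first sample in seconds.
    label : str
        Channel name, e.g. ``"rip"`` or ``"chestmid_x"``.
    units : str
        Physical units: ``"mm"`` for EMA coordinates/distances, ``"norm"``
        for max-abs normalized signals, ``"au"`` otherwise.
    """

    values: np.ndarray
    rate_hz: float
    start_s: float = 0.0
    label: str = ""
    units: str = "au"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"TimeSeries values must be 1-D, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("TimeSeries must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"TimeSeries {self.label!r} contains non-finite values")
        if not (self.rate_hz > 0):
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Span between first and last sample: ``(n - 1) / rate_hz``."""
        return (len(self) - 1) / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(len(self)) / self.rate_hz

    def index_at(self, t_s: float, clip: bool = False) -> int:
        """Nearest sample index for time ``t_s``."""
        i = int(round((t_s - self.start_s) * self.rate_hz))
        if clip:
            return min(max(i, 0), len(self) - 1)
        if not (0 <= i < len(self)):
            raise IndexError(f"time {t_s} s outside support [{self.start_s}, {self.end_s}] s")
        return i

    def time_at(self, i: int) -> float:
        return self.start_s + i / self.rate_hz

    def slice_time(self, t0_s: float, t1_s: float) -> "TimeSeries":
        """Sub-series over ``[t0_s, t1_s]`` clipped to support (inclusive ends)."""
        if t1_s < t0_s:
            raise ValueError("slice_time requires t0 <= t1")
        i0 = max(0, int(np.ceil((t0_s - self.start_s) * self.rate_hz - 1e-9)))
        i1 = min(len(self) - 1, int(np.floor((t1_s - self.start_s) * self.rate_hz + 1e-9)))
        if i1 < i0:
            raise DegenerateInputError(
                f"window [{t0_s}, {t1_s}] s does not intersect support "
                f"[{self.start_s}, {self.end_s}] s"
            )
        return replace(self, values=self.values[i0 : i1 + 1], start_s=self.time_at(i0))

    def with_values(self, values: np.ndarray, rate_hz: float | None = None,
                    units: str | None = None) -> "TimeSeries":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            rate_hz=self.rate_hz if rate_hz is None else rate_hz,
            units=self.units if units is None else units,
        )

    def shifted(self, dt_s: float) -> "TimeSeries":
        return replace(self, start_s=self.start_s + dt_s)


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s):
            raise ValueError(
                f"interval must satisfy start < end, got [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class IntervalTier:
    """Ordered, non-overlapping labelled intervals (one Praat interval tier)."""

    name: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"tier {self.name!r}: overlapping intervals "
                    f"[{a.start_s}, {a.end_s}] and [{b.start_s}, {b.end_s}]"
                )
        self.intervals = ivs

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def labelled(self, label: str | None = None) -> list[Interval]:
        """Intervals with a non-empty label (or exactly ``label`` if given)."""
        if label is None:
            return [iv for iv in self.intervals if iv.label.strip()]
        return [iv for iv in self.intervals if iv.label == label]

    def shifted(self, dt_s: float) -> "IntervalTier":
        return IntervalTier(
            self.name,
            [Interval(iv.start_s + dt_s, iv.end_s + dt_s, iv.label) for iv in self.intervals],
        )


def as_float_array(x: Sequence[float] | np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float)
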