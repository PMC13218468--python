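"""EMA sensor-distance measures.

Five sensors track chest-wall kinematics: a reference on the lowest cervical
vertebra plus sternum, chest-mid, chest-left and chest-right sensors.  Three
distance measures are computed against the reference, each per coordinate
dimension (x = front-back, y = low-high):

    D_chestmid  = chestmid - ref
    D_midpoint  = (chestleft + chestright) / 2 - ref
    D_sternum   = sternum - ref

These are signed coordinate differences, not Euclidean norms; the z
coordinate is carried but unused, matching the 2-D analysis.  Device axes
are mapped to the named roles by configuration since mounting conventions
vary between sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import TimeSeries
from .errors import ConfigurationError

__all__ = ["SENSOR_ROLES", "MEASURES", "DIMS", "SensorFrameSet", "DistanceSeries",
           "compute_distance", "all_distances"]

SENSOR_ROLES = ("ref", "sternum", "chestmid", "chestleft", "chestright")
MEASURES = ("chestmid", "midpoint", "sternum")
DIMS = ("x", "y")


@dataclass
class SensorFrameSet:
    """Time-aligned x/y/z trajectories for the five named sensors.

    ``sensors`` maps role -> {dim -> TimeSeries}; all series must share the
    sampling rate, start time and length.
    """

    sensors: dict[str, dict[str, TimeSeries]]

    def __post_init__(self) -> None:
        missing = [r for r in SENSOR_ROLES if r not in self.sensors]
        if missing:
            raise ConfigurationError(f"missing sensor roles: {missing}")
        ref = self.sensors["ref"]["x"]
        for role, dims in self.sensors.items():
            for dim, ts in dims.items():
                if len(ts) != len(ref) or abs(ts.rate_hz - ref.rate_hz) > 1e-9 \
                        or abs(ts.start_s - ref.start_s) > 1e-9:
                    raise ConfigurationError(
                        f"sensor {role}.{dim} is not time-aligned with the reference"
                    )

    @property
    def rate_hz(self) -> float:
        return self.sensors["ref"]["x"].rate_hz

    @property
    def start_s(self) -> float:
        return self.sensors["ref"]["x"].start_s

    def coord(self, role: str, dim: str) -> TimeSeries:
        try:
            return self.sensors[role][dim]
        except KeyError:
            raise ConfigurationError(f"sensor {role!r} has no {dim!r} coordinate") from None

    @classmethod
    def from_mapping(
        cls,
        series: Mapping[str, TimeSeries],
        role_map: Mapping[str, str] | None = None,
    ) -> "SensorFrameSet":
        """Build from flat labels like ``"ref_x"`` with an optional
        label -> ``role_dim`` rename map."""
        sensors: dict[str, dict[str, TimeSeries]] = {}
        for label, ts in series.items():
            name = role_map.get(label, label) if role_map else label
            if "_" not in name:
                raise ConfigurationError(f"cannot split {name!r} into role_dim")
            role, dim = name.rsplit("_", 1)
            sensors.setdefault(role, {})[dim] = ts
        return cls(sensors)


@dataclass(frozen=True)
class DistanceSeries:
    """One analysis channel: a distance measure along one dimension."""

    measure_id: str
    dim: str
    series: TimeSeries = field(compare=False)

    @property
    def channel(self) -> str:
        return f"{self.measure_id}_{self.dim}"


def compute_distance(frames: SensorFrameSet, measure_id: str, dim: str) -> DistanceSeries:
    """Compute one distance measure along one coordinate dimension (mm)."""
    if measure_id not in MEASURES:
        raise ConfigurationError(f"unknown measure {measure_id!r}; expected one of {MEASURES}")
    if dim not in ("x", "y", "z"):
        raise ConfigurationError(f"unknown dimension {dim!r}")
    ref = frames.coord("ref", dim)
    if measure_id == "chestmid":
        vals = frames.coord("chestmid", dim).values - ref.values
    elif measure_id == "sternum":
        vals = frames.coord("sternum", dim).values - ref.values
    else:  # midpoint of the left and right chest sensors
        left = frames.coord("chestleft", dim).values
        right = frames.coord("chestright", dim).values
        vals = 0.5 * (left + right) - ref.values
    ts = TimeSeries(np.asarray(vals), rate_hz=frames.rate_hz, start_s=frames.start_s,
                    label=f"D_{measure_id},{dim}", units="mm")
    return DistanceSeries(measure_id, dim, ts)


def all_distances(frames: SensorFrameSet) -> list[DistanceSeries]:
    """The six analysis channels: each measure x each of x, y."""
    return [compute_distance(frames, m, d) for m in MEASURES for d in DIMS]
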