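"""Shared domain types for CA1/PFC session analysis.

All times are seconds from a common session zero; intervals are half-open
``[start, end)``.  Physical units are cm, cm/s, Hz and µV throughout; any
conversion happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SpikeTrain",
    "PositionTrace",
    "LfpBundle",
    "WellGeometry",
    "WellEvent",
    "Session",
    "ValidationError",
]


class ValidationError(ValueError):
    """A session component violated one of its structural invariants."""


@dataclass
class SpikeTrain:
    """Ordered spike times for one unit.

    Parameters
    ----------
    unit_id : str
        Unique identifier of the unit within the session.
    region : str
        ``"CA1"`` or ``"PFC"``.
    spike_times_s : ndarray
        Strictly increasing spike times in seconds.
    spike_width_ms : float
        Mean waveform width in milliseconds (> 0); used to separate
        putative pyramidal cells from fast-spiking interneurons.
    """

    unit_id: str
    region: str
    spike_times_s: np.ndarray
    spike_width_ms: float

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.region not in ("CA1", "PFC"):
            raise ValidationError(
                f"unit {self.unit_id}: region must be CA1 or PFC, got {self.region!r}"
            )
        if self.spike_times_s.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike times must be 1-D")
        if self.spike_times_s.size and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )
        if not self.spike_width_ms > 0:
            raise ValidationError(f"unit {self.unit_id}: spike_width_ms must be > 0")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def mean_rate_hz(self, duration_s: float) -> float:
        return self.n_spikes / duration_s if duration_s > 0 else float("nan")


@dataclass
class PositionTrace:
    """Time-stamped 2-D position in cm, with an optional derived speed."""

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    speed_cm_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        n = self.time_s.size
        if self.x_cm.size != n or self.y_cm.size != n:
            raise ValidationError("position: time/x/y lengths differ")
        if n >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("position: time must be strictly increasing")
        if self.speed_cm_s is not None:
            self.speed_cm_s = np.asarray(self.speed_cm_s, dtype=float)
            if self.speed_cm_s.size != n:
                raise ValidationError("position: speed length differs from time")
            if np.any(self.speed_cm_s < 0):
                raise ValidationError("position: speed must be nonnegative")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.time_s.size >= 2 else 0.0


@dataclass
class LfpBundle:
    """Aligned multi-channel LFP matrix (time × channel, µV)."""

    sample_rate_hz: float
    channel_ids: list[str]
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz < 1000:
            raise ValidationError(
                f"lfp: sample_rate_hz must be >= 1000, got {self.sample_rate_hz}"
            )
        if self.samples.ndim != 2:
            raise ValidationError("lfp: samples must be a 2-D (time x channel) matrix")
        if self.samples.shape[1] != len(self.channel_ids):
            raise ValidationError(
                f"lfp: {self.samples.shape[1]} columns but "
                f"{len(self.channel_ids)} channel ids"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[1])

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class WellGeometry:
    """Location and capture radius of one reward well."""

    well_id: str
    x_cm: float
    y_cm: float
    radius_cm: float = 10.0

    def __post_init__(self) -> None:
        if not self.radius_cm > 0:
            raise ValidationError(f"well {self.well_id}: radius_cm must be > 0")


@dataclass
class WellEvent:
    """A beam-break style well entry or exit."""

    time_s: float
    well_id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("entry", "exit"):
            raise ValidationError(f"well event kind must be entry|exit, got {self.kind!r}")


@dataclass
class Session:
    """Container for one recording session.

    Invariants: all times on a common zero; spike times strictly increasing
    per unit; every well id referenced by an event exists in ``wells``.
    """

    position: PositionTrace
    units: list[SpikeTrain]
    lfp: LfpBundle
    wells: list[WellGeometry]
    well_events: list[WellEvent] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        well_ids = {w.well_id for w in self.wells}
        if len(well_ids) != len(self.wells):
            raise ValidationError("session: duplicate well ids")
        coords = {(w.x_cm, w.y_cm) for w in self.wells}
        if len(coords) != len(self.wells):
            raise ValidationError("session: well positions must be distinct")
        for ev in self.well_events:
            if ev.well_id not in well_ids:
                raise ValidationError(f"well event references unknown well {ev.well_id!r}")
        unit_ids = [u.unit_id for u in self.units]
        if len(set(unit_ids)) != len(unit_ids):
            raise ValidationError("session: duplicate unit ids")

    @property
    def duration_s(self) -> float:
        return self.position.duration_s

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def units_in(self, region: str) -> list[SpikeTrain]:
        return [u for u in self.units if u.region == region]


def spikes_in_intervals(spike_times_s: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask of spikes falling in any half-open interval [start, end).

    ``intervals`` is an (n, 2) array; it need not be sorted but must be
    non-overlapping for the mask to be meaningful.
    """
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    intervals = np.atleast_2d(np.asarray(intervals, dtype=float))
    if intervals.size == 0:
        return np.zeros(spike_times_s.size, dtype=bool)
    order = np.argsort(intervals[:, 0])
    starts, ends = intervals[order, 0], intervals[order, 1]
    idx = np.searchsorted(starts, spike_times_s, side="right") - 1
    ok = idx >= 0
    mask = np.zeros(spike_times_s.size, dtype=bool)
    mask[ok] = spike_times_s[ok] < ends[idx[ok]]
    return mask


def total_interval_time(intervals: np.ndarray) -> float:
    intervals = np.atleast_2d(np.asarray(intervals, dtype=float))
    if intervals.size == 0:
        return 0.0
    return float(np.sum(intervals[:, 1] - intervals[:, 0]))


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection of two sorted, non-overlapping interval sets."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=float).reshape(-1, 2)


def subtract_intervals(base: np.ndarray, remove: np.ndarray) -> np.ndarray:
    """Set difference base \\ remove over sorted non-overlapping intervals."""
    base = np.atleast_2d(np.asarray(base, dtype=float))
    remove = np.atleast_2d(np.asarray(remove, dtype=float))
    if remove.size == 0:
        return base.reshape(-1, 2)
    out = []
    for lo, hi in base:
        cur = lo
        for rlo, rhi in remove:
            if rhi <= cur or rlo >= hi:
                continue
            if rlo > cur:
                out.append((cur, rlo))
            cur = max(cur, rhi)
            if cur >= hi:
                break
        if cur < hi:
            out.append((cur, hi))
    return np.array(out, dtype=float).reshape(-1, 2)
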