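"""Behavioral state analysis: speed, movement/immobility segmentation,
well occupancy and occupancy maps.

Movement is defined as speed > 4 cm/s of the tracked position; immobility
is everything else.  Intervals are half-open ``[start, end)`` and tile the
tracked portion of the session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .model import (
    PositionTrace,
    Session,
    ValidationError,
    intersect_intervals,
)

__all__ = [
    "MotionSegmentation",
    "OccupancyMap",
    "compute_speed",
    "segment_motion",
    "well_occupancy_intervals",
    "at_well_intervals",
    "occupancy_map",
]


@dataclass
class MotionSegmentation:
    """Alternating movement/immobility intervals tiling the session."""

    intervals: list[tuple[str, float, float]]  # (state, start_s, end_s)
    speed_threshold_cm_s: float = 4.0

    def intervals_of(self, state: str) -> np.ndarray:
        out = [(s, e) for st, s, e in self.intervals if st == state]
        return np.array(out, dtype=float).reshape(-1, 2)

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """State label for each query time ('movement'/'immobility')."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        starts = np.array([s for _, s, _ in self.intervals])
        labels = np.array([st for st, _, _ in self.intervals])
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(starts) - 1)
        return labels[idx]


@dataclass
class OccupancyMap:
    """Time spent per 2-D spatial bin (seconds)."""

    bin_edges_x_cm: np.ndarray
    bin_edges_y_cm: np.ndarray
    seconds_per_bin: np.ndarray

    @property
    def total_s(self) -> float:
        return float(self.seconds_per_bin.sum())


def compute_speed(position: PositionTrace, smoothing_sigma_s: float = 0.25) -> np.ndarray:
    """Estimate speed (cm/s) per position sample.

    Central differences of position (one-sided at the edges) followed by
    Gaussian temporal smoothing; the smoothing suppresses frame-jitter
    flicker across the 4 cm/s movement threshold.
    """
    t = position.time_s
    if t.size < 3:
        raise ValidationError("compute_speed: need at least 3 position samples")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("compute_speed: time must be strictly increasing")
    vx = np.gradient(position.x_cm, t)
    vy = np.gradient(position.y_cm, t)
    speed = np.hypot(vx, vy)
    if smoothing_sigma_s > 0:
        dt = float(np.median(np.diff(t)))
        sigma_samples = smoothing_sigma_s / dt
        if sigma_samples > 0.1:
            speed = gaussian_filter1d(speed, sigma_samples, mode="nearest")
    return np.maximum(speed, 0.0)


def segment_motion(
    position: PositionTrace,
    speed: np.ndarray | None = None,
    threshold_cm_s: float = 4.0,
) -> MotionSegmentation:
    """Split the session into alternating movement/immobility intervals.

    A sample is 'movement' when its speed exceeds ``threshold_cm_s``.  Each
    interval runs from its first sample to the first sample of the next
    interval (the last one ends at the last sample time).
    """
    if speed is None:
        speed = position.speed_cm_s
    if speed is None:
        speed = compute_speed(position)
    t = position.time_s
    moving = np.asarray(speed) > threshold_cm_s
    # boundaries where state changes
    change = np.flatnonzero(np.diff(moving.astype(int)) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(t) - 1]])
    intervals = []
    for s_idx, e_idx in zip(starts, ends):
        state = "movement" if moving[s_idx] else "immobility"
        start = float(t[s_idx])
        end = float(t[e_idx]) if e_idx == len(t) - 1 else float(t[e_idx])
        intervals.append((state, start, end))
    # last interval must reach session end; drop zero-length intervals
    intervals = [(st, s, e) for st, s, e in intervals if e > s]
    return MotionSegmentation(intervals, threshold_cm_s)


def at_well_intervals(session: Session, well_id: str) -> np.ndarray:
    """Intervals during which the animal is at a given well.

    A time is 'at the well' if it lies between a recorded entry and exit
    event for that well; outside recorded events, position within the
    well's capture radius counts.  Recorded events take precedence.
    """
    wells = {w.well_id: w for w in session.wells}
    if well_id not in wells:
        raise KeyError(f"unknown well id {well_id!r}")
    w = wells[well_id]
    t = session.position.time_s

    event_iv = []
    entry_time = None
    for ev in sorted(session.well_events, key=lambda e: e.time_s):
        if ev.well_id != well_id:
            continue
        if ev.kind == "entry":
            entry_time = ev.time_s
        elif ev.kind == "exit" and entry_time is not None:
            event_iv.append((entry_time, ev.time_s))
            entry_time = None
    if entry_time is not None:
        event_iv.append((entry_time, float(t[-1])))

    # radius-based intervals from position samples
    near = np.hypot(session.position.x_cm - w.x_cm, session.position.y_cm - w.y_cm) <= w.radius_cm
    radius_iv = _mask_to_intervals(t, near)

    merged = _merge_intervals(np.array(event_iv).reshape(-1, 2), radius_iv)
    return merged


def _mask_to_intervals(t: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return np.empty((0, 2))
    iv = []
    idx = np.flatnonzero(mask)  # runs of consecutive True indices
    splits = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[splits + 1]])
    run_ends = np.concatenate([idx[splits], [idx[-1]]])
    for rs, re in zip(run_starts, run_ends):
        iv.append((float(t[rs]), float(t[min(re + 1, len(t) - 1)])))
    return np.array(iv).reshape(-1, 2)


def _merge_intervals(*sets: np.ndarray) -> np.ndarray:
    allv = np.vstack([s.reshape(-1, 2) for s in sets if s.size])
    if allv.size == 0:
        return np.empty((0, 2))
    allv = allv[np.argsort(allv[:, 0])]
    out = [list(allv[0])]
    for lo, hi in allv[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return np.array(out)


def well_occupancy_intervals(
    session: Session, segmentation: MotionSegmentation
) -> dict[str, np.ndarray]:
    """Per-well intervals of immobility at that well.

    Intersection of the immobility intervals with at-well occupancy; this
    is the exposure used for immobility firing-rate criteria.
    """
    immobile = segmentation.intervals_of("immobility")
    return {
        w.well_id: intersect_intervals(immobile, at_well_intervals(session, w.well_id))
        for w in session.wells
    }


def occupancy_map(
    position: PositionTrace,
    bin_cm: float = 2.0,
    bin_edges_x: np.ndarray | None = None,
    bin_edges_y: np.ndarray | None = None,
) -> OccupancyMap:
    """Time spent in each 2 cm square spatial bin.

    Each inter-sample interval's duration is credited to the bin of its
    starting sample, so the total over bins equals the tracked duration
    exactly (to the final frame).
    """
    t, x, y = position.time_s, position.x_cm, position.y_cm
    def _edges(v: np.ndarray) -> np.ndarray:
        lo = np.floor(v.min() / bin_cm) * bin_cm
        hi = np.ceil(v.max() / bin_cm) * bin_cm
        if hi <= lo:  # constant coordinate sitting on a bin edge
            hi = lo + bin_cm
        return np.arange(lo, hi + bin_cm / 2, bin_cm)

    if bin_edges_x is None:
        bin_edges_x = _edges(x)
    if bin_edges_y is None:
        bin_edges_y = _edges(y)
    dt = np.diff(t)
    H, _, _ = np.histogram2d(
        x[:-1], y[:-1], bins=[bin_edges_x, bin_edges_y], weights=dt
    )
    return OccupancyMap(bin_edges_x, bin_edges_y, H)
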