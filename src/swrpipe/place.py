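"""CA1 unit classification and spatial firing properties.

Putative pyramidal cells are separated from fast-spiking interneurons by
spike width (< 0.4 ms) and mean rate (>= 10 Hz).  Pyramidal units with
more than 200 spikes are classified as immobility-associated place cells
(IAPs) if their mean rate during immobility at some reward well, with
SWR spikes excluded, reaches 3 Hz; the remainder are movement-associated
place cells (MAPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .behavior import OccupancyMap
from .model import (
    PositionTrace,
    SpikeTrain,
    spikes_in_intervals,
    subtract_intervals,
    total_interval_time,
)
from .ripples import SwrEvent

__all__ = [
    "RateMap",
    "WellTuning",
    "UnitClassification",
    "classify_cell_class",
    "rate_map",
    "immobility_well_rates",
    "classify_place_class",
    "well_specificity",
    "median_speed_per_spike",
    "place_coverage",
]


@dataclass
class RateMap:
    """Occupancy-normalized, Gaussian-smoothed firing-rate map (Hz per 2 cm bin).

    Bins the animal never occupied are NaN, not zero.
    """

    rate_hz: np.ndarray
    bin_edges_x_cm: np.ndarray
    bin_edges_y_cm: np.ndarray

    @property
    def peak_rate_hz(self) -> float:
        return float(np.nanmax(self.rate_hz))


@dataclass
class WellTuning:
    per_well_rate_hz: dict[str, float]
    specificity: float
    preferred_well: str


@dataclass
class UnitClassification:
    unit_id: str
    cell_class: str          # pyramidal | interneuron
    place_class: str         # IAP | MAP | excluded
    preferred_well: str | None = None
    specificity: float = float("nan")
    median_speed_cm_s: float = float("nan")
    coverage: float = float("nan")


def classify_cell_class(spike_width_ms: float, mean_rate_hz: float,
                        max_width_ms: float = 0.4, min_rate_hz: float = 10.0) -> str:
    """Interneuron iff narrow spike (< 0.4 ms) or high mean rate (>= 10 Hz)."""
    if spike_width_ms < max_width_ms or mean_rate_hz >= min_rate_hz:
        return "interneuron"
    return "pyramidal"


def rate_map(
    spikes: SpikeTrain | np.ndarray,
    occupancy: OccupancyMap,
    position: PositionTrace,
    sigma_cm: float = 2.0,
    extent_cm: float = 12.0,
) -> RateMap:
    """Occupancy-normalized rate map: smoothed spike counts / smoothed occupancy.

    Spike positions are linearly interpolated from the position trace.
    Smoothing uses a symmetric 2-D Gaussian (sigma = 2 cm, truncated to a
    12 cm extent).  Bins with zero occupancy are NaN.
    """
    times = spikes.spike_times_s if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    t = position.time_s
    if times.size and (times.min() < t[0] or times.max() > t[-1]):
        raise ValueError("spike outside tracked time range")
    sx = np.interp(times, t, position.x_cm)
    sy = np.interp(times, t, position.y_cm)
    counts, _, _ = np.histogram2d(
        sx, sy, bins=[occupancy.bin_edges_x_cm, occupancy.bin_edges_y_cm]
    )
    bin_cm = float(occupancy.bin_edges_x_cm[1] - occupancy.bin_edges_x_cm[0])
    sigma_bins = sigma_cm / bin_cm
    # truncate kernel to the requested spatial extent (half-width / sigma)
    truncate = (extent_cm / 2.0) / sigma_cm
    sm_counts = gaussian_filter(counts, sigma_bins, truncate=truncate)
    sm_occ = gaussian_filter(occupancy.seconds_per_bin, sigma_bins, truncate=truncate)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = sm_counts / sm_occ
    rate[occupancy.seconds_per_bin == 0] = np.nan
    return RateMap(rate, occupancy.bin_edges_x_cm, occupancy.bin_edges_y_cm)


def immobility_well_rates(
    spikes: SpikeTrain | np.ndarray,
    well_intervals: dict[str, np.ndarray],
    swr_events: list[SwrEvent],
) -> dict[str, float]:
    """Mean firing rate during immobility at each well, SWR spikes excluded.

    For each well: spikes inside the well's immobility intervals but
    outside every SWR, divided by the interval time minus SWR time.  Wells
    with no eligible time get NaN.
    """
    times = spikes.spike_times_s if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    swr_iv = np.array([[e.start_s, e.end_s] for e in swr_events], dtype=float).reshape(-1, 2)
    swr_iv = swr_iv[np.argsort(swr_iv[:, 0])] if swr_iv.size else swr_iv
    rates: dict[str, float] = {}
    for well_id, iv in well_intervals.items():
        iv = np.asarray(iv, dtype=float).reshape(-1, 2)
        eligible = subtract_intervals(iv, swr_iv)
        t_total = total_interval_time(eligible)
        if t_total <= 0:
            rates[well_id] = float("nan")
            continue
        n = int(spikes_in_intervals(times, eligible).sum())
        rates[well_id] = n / t_total
    return rates


def classify_place_class(
    well_rates: dict[str, float],
    total_spikes: int,
    min_spikes: int = 200,
    iap_min_rate_hz: float = 3.0,
) -> str:
    """IAP if any well rate reaches 3 Hz; MAP otherwise; excluded if <= 200 spikes."""
    if total_spikes <= min_spikes:
        return "excluded"
    finite = [r for r in well_rates.values() if np.isfinite(r)]
    if finite and max(finite) >= iap_min_rate_hz:
        return "IAP"
    return "MAP"


def well_specificity(per_well_rates: np.ndarray) -> float:
    """Well specificity index in [0, 1].

    Rates are normalized to their maximum and treated as weights on unit
    vectors equally spaced on the circle (90 degrees apart for four
    wells); the index is the length of the resultant divided by the total
    weight.  1 means the cell fires at a single well only; 0 means equal
    rates at all wells.
    """
    r = np.asarray(per_well_rates, dtype=float)
    r = np.where(np.isfinite(r), r, 0.0)
    if r.size < 2:
        raise ValueError("need at least two wells")
    if r.max() <= 0:
        return float("nan")
    rn = r / r.max()
    angles = 2 * np.pi * np.arange(r.size) / r.size
    vx = float(np.sum(rn * np.cos(angles)))
    vy = float(np.sum(rn * np.sin(angles)))
    out = float(np.hypot(vx, vy) / rn.sum())
    if out < 1e-12:  # cancel trig round-off for exactly balanced rates
        return 0.0
    return min(out, 1.0)


def median_speed_per_spike(
    spikes: SpikeTrain | np.ndarray, position: PositionTrace, speed: np.ndarray
) -> float:
    """Median of the animal's speed interpolated at each spike time."""
    times = spikes.spike_times_s if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    if times.size == 0:
        return float("nan")
    return float(np.median(np.interp(times, position.time_s, speed)))


def place_coverage(
    ratemap: RateMap,
    occupancy: OccupancyMap,
    threshold_frac: float = 0.2,
    min_occupancy_s: float = 0.1,
) -> float:
    """Fraction of occupied bins whose rate reaches 20% of the map peak.

    Occupied means at least ``min_occupancy_s`` seconds in the bin.
    """
    occupied = occupancy.seconds_per_bin >= min_occupancy_s
    if not occupied.any():
        return float("nan")
    peak = np.nanmax(ratemap.rate_hz[occupied]) if occupied.any() else np.nan
    if not np.isfinite(peak) or peak <= 0:
        return 0.0
    active = (ratemap.rate_hz >= threshold_frac * peak) & occupied
    return float(active.sum() / occupied.sum())
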