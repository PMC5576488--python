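"""Spike-train correlation measures.

Cross-/auto-correlograms use nearest-center binning: a spike-time
difference d falls in the bin whose center ``k * bin_s`` minimizes
``|d - k * bin_s|`` (ties resolved to the even index), so the correlogram
is exactly symmetric under exchange of the two trains with lag negation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .model import spikes_in_intervals

__all__ = [
    "Correlogram",
    "Peth",
    "cross_correlogram",
    "auto_correlogram",
    "nearby_spike_proportion",
    "well_entry_peth",
    "pattern_similarity_index",
    "coincidence_index",
    "zero_lag_z",
]


@dataclass
class Correlogram:
    """Histogram of pairwise lags t_b - t_a, normalized to sum 1."""

    lags_s: np.ndarray
    values: np.ndarray
    n_events: int          # coincident spike pairs inside the window
    eligible: bool         # n_events > 100

    @property
    def peak_lag_s(self) -> float:
        if self.values.sum() == 0:
            return float("nan")
        return float(self.lags_s[int(np.argmax(self.values))])


@dataclass
class Peth:
    """Peri-event time histogram over a symmetric window."""

    lags_s: np.ndarray
    rate_hz: np.ndarray
    normalized_rate: np.ndarray
    active: bool


def _pair_lags(a: np.ndarray, b: np.ndarray, half_window_s: float) -> np.ndarray:
    """All lags t_b - t_a with |lag| <= half_window_s (a, b sorted)."""
    lo = np.searchsorted(b, a - half_window_s, side="left")
    hi = np.searchsorted(b, a + half_window_s, side="right")
    lengths = hi - lo
    total = int(lengths.sum())
    if total == 0:
        return np.empty(0)
    rep_a = np.repeat(a, lengths)
    offsets = np.repeat(np.cumsum(lengths) - lengths, lengths)
    ii = np.arange(total) - offsets + np.repeat(lo, lengths)
    return b[ii] - rep_a


def cross_correlogram(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    bin_s: float = 0.010,
    window_s: float = 1.0,
    min_coincidences: int = 100,
    remove_zero_lag: bool = False,
) -> Correlogram:
    """Normalized histogram of lags of train b relative to train a.

    Bin centers are at integer multiples of ``bin_s`` spanning
    ``[-window_s/2, window_s/2]``; each bin's count is divided by the sum
    over all bins.  Pairs with ``min_coincidences`` or fewer coincident
    events are flagged ineligible.
    """
    a = np.asarray(spikes_a, dtype=float)
    b = np.asarray(spikes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both spike trains must be nonempty")
    half = window_s / 2.0
    n_half = int(round(half / bin_s))
    centers = np.arange(-n_half, n_half + 1) * bin_s

    lags = _pair_lags(a, b, half + bin_s / 2.0)
    if remove_zero_lag:
        lags = lags[lags != 0.0]
    idx = np.rint(lags / bin_s).astype(int)
    keep = np.abs(idx) <= n_half
    idx = idx[keep] + n_half
    counts = np.bincount(idx, minlength=centers.size).astype(float)
    n_events = int(counts.sum())
    values = counts / n_events if n_events > 0 else counts
    return Correlogram(centers, values, n_events, n_events > min_coincidences)


def auto_correlogram(
    spikes: np.ndarray,
    bin_s: float = 0.010,
    window_s: float = 1.0,
    speed_at_spikes: np.ndarray | None = None,
    speed_range: tuple[float, float] | None = None,
    min_coincidences: int = 100,
) -> Correlogram:
    """Auto-correlogram with zero-lag self-pairs removed.

    Optionally restricts to spikes whose concurrent running speed lies in
    ``speed_range`` (e.g. ``(4, inf)`` for movement, ``(0, 1)`` for strict
    immobility).
    """
    spikes = np.asarray(spikes, dtype=float)
    if speed_range is not None:
        if speed_at_spikes is None:
            raise ValueError("speed_at_spikes required when speed_range is given")
        lo, hi = speed_range
        spikes = spikes[(speed_at_spikes > lo) & (speed_at_spikes < hi)]
    if spikes.size == 0:
        raise ValueError("no spikes after state filtering")
    return cross_correlogram(
        spikes, spikes, bin_s, window_s, min_coincidences, remove_zero_lag=True
    )


def nearby_spike_proportion(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    near_s: float = 0.050,
    far_s: float = 3.3,
) -> float:
    """Proportion of spikes with a partner spike nearby.

    For each direction: the number of a-spikes with at least one b-spike
    within +/- ``near_s``, divided by the number with at least one within
    +/- ``far_s``; the two directions are averaged.  NaN when neither
    direction has a far coincidence.
    """
    a = np.sort(np.asarray(spikes_a, dtype=float))
    b = np.sort(np.asarray(spikes_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both spike trains must be nonempty")

    def one_way(x: np.ndarray, y: np.ndarray) -> float:
        near = (
            np.searchsorted(y, x + near_s, side="right")
            > np.searchsorted(y, x - near_s, side="left")
        )
        far = (
            np.searchsorted(y, x + far_s, side="right")
            > np.searchsorted(y, x - far_s, side="left")
        )
        denom = int(far.sum())
        return near.sum() / denom if denom > 0 else float("nan")

    vals = [one_way(a, b), one_way(b, a)]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def well_entry_peth(
    spikes: np.ndarray,
    entry_times: np.ndarray,
    window_s: float = 5.0,
    bin_s: float = 0.1,
    smoothing_sigma_s: float = 0.1,
) -> Peth:
    """Mean firing rate around well entries, normalized to its window maximum."""
    entry_times = np.atleast_1d(np.asarray(entry_times, dtype=float))
    if entry_times.size == 0:
        raise ValueError("need at least one well entry")
    lags = _pair_lags(np.sort(entry_times), np.sort(np.asarray(spikes, dtype=float)),
                      window_s + bin_s / 2.0)
    n_half = int(round(window_s / bin_s))
    centers = np.arange(-n_half, n_half + 1) * bin_s
    idx = np.rint(lags / bin_s).astype(int)
    idx = idx[np.abs(idx) <= n_half] + n_half
    counts = np.bincount(idx, minlength=centers.size).astype(float)
    rate = counts / (entry_times.size * bin_s)
    if smoothing_sigma_s > 0:
        rate = gaussian_filter1d(rate, smoothing_sigma_s / bin_s, mode="nearest")
    peak = rate.max()
    active = peak > 0
    norm = rate / peak if active else rate
    return Peth(centers, rate, norm, active)


def pattern_similarity_index(
    pfc_peth: Peth,
    iap_peths: list[Peth],
    map_peths: list[Peth],
) -> np.ndarray:
    """Pairwise differences corr(PFC, IAP) - corr(PFC, MAP).

    Positive values mean the PFC unit's well-entry firing pattern is more
    IAP-like; negative, more MAP-like.  Pairings involving a constant
    PETH are skipped.
    """
    p = pfc_peth.rate_hz
    if np.std(p) == 0:
        return np.empty(0)
    iap_corr = [_corr(p, q.rate_hz) for q in iap_peths]
    map_corr = [_corr(p, q.rate_hz) for q in map_peths]
    out = [
        ci - cm
        for ci in iap_corr
        if np.isfinite(ci)
        for cm in map_corr
        if np.isfinite(cm)
    ]
    return np.asarray(out, dtype=float)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def zero_lag_z(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    exclude_intervals: np.ndarray | None = None,
    bin_s: float = 0.1,
    window_s: float = 20.0,
    min_coincidences: int = 100,
) -> float:
    """Z-scored zero-lag cross-correlation value for one cell pair.

    The cross-correlogram (100 ms bins over a 20 s window by default,
    spikes inside ``exclude_intervals`` dropped first) is normalized by
    subtracting the mean and dividing by the SD of all bins; the value of
    the bin centered at 0 s lag is returned.  NaN for ineligible pairs.
    """
    a = np.asarray(spikes_a, dtype=float)
    b = np.asarray(spikes_b, dtype=float)
    if exclude_intervals is not None and np.asarray(exclude_intervals).size:
        a = a[~spikes_in_intervals(a, exclude_intervals)]
        b = b[~spikes_in_intervals(b, exclude_intervals)]
    if a.size == 0 or b.size == 0:
        return float("nan")
    cg = cross_correlogram(a, b, bin_s, window_s, min_coincidences)
    if not cg.eligible:
        return float("nan")
    counts = cg.values * cg.n_events
    sd = counts.std()
    if sd == 0:
        return float("nan")
    z = (counts - counts.mean()) / sd
    return float(z[counts.size // 2])


def coincidence_index(
    pfc_spikes: np.ndarray,
    iap_spike_trains: list[np.ndarray],
    map_spike_trains: list[np.ndarray],
    exclude_intervals: np.ndarray | None = None,
    bin_s: float = 0.1,
    window_s: float = 20.0,
    min_coincidences: int = 100,
) -> np.ndarray:
    """Pairwise differences of zero-lag z between PFC-IAP and PFC-MAP pairs.

    Positive values indicate spiking more coincident with IAPs than MAPs
    outside ripples.  Ineligible pairings (too few coincidences) are
    skipped.
    """
    z_iap = [
        zero_lag_z(pfc_spikes, s, exclude_intervals, bin_s, window_s, min_coincidences)
        for s in iap_spike_trains
    ]
    z_map = [
        zero_lag_z(pfc_spikes, s, exclude_intervals, bin_s, window_s, min_coincidences)
        for s in map_spike_trains
    ]
    out = [
        zi - zm
        for zi in z_iap
        if np.isfinite(zi)
        for zm in z_map
        if np.isfinite(zm)
    ]
    return np.asarray(out, dtype=float)
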