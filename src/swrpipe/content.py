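"""Ripple content classification and coactivity statistics.

Each detected ripple is labeled by the place-cell types spiking within it
(MAP-only, IAP-only, joint, or neither).  Count statistics compare the
observed number of joint events with the expectation under independent
MAP/IAP participation; pairwise coactivity is measured against a
permutation null that shuffles each unit's participation across events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .correlate import cross_correlogram
from .ripples import SwrEvent

__all__ = [
    "ContentCounts",
    "CoactivityResult",
    "assign_content",
    "content_counts",
    "participation_matrix",
    "coactivity_z",
    "pair_eligibility",
    "in_swr_latency",
    "event_property_summary",
]


@dataclass
class ContentCounts:
    n_map_only: int
    n_iap_only: int
    n_joint: int
    expected_joint: float
    expected_joint_rounded: int
    chi2_stat: float
    p_value: float

    @property
    def n_total(self) -> int:
        return self.n_map_only + self.n_iap_only + self.n_joint


@dataclass
class CoactivityResult:
    pair: tuple[str, str]
    observed_joint_fraction: float
    null_mean: float
    null_sd: float
    z: float
    n_permutations: int
    seed: int
    degenerate: bool = False


def assign_content(
    events: list[SwrEvent],
    place_class_by_unit: dict[str, str],
    spikes_by_unit: dict[str, np.ndarray],
) -> list[SwrEvent]:
    """Label each event with its participants and content class.

    A unit participates in an event if it has at least one spike in
    ``[start, end)``.  Events containing only MAPs are MAP-only, only
    IAPs are IAP-only, both are joint, and none of either type are
    'neither'.  Events are modified in place and returned.
    """
    place_units = {
        u: c for u, c in place_class_by_unit.items() if c in ("IAP", "MAP")
    }
    starts = np.array([e.start_s for e in events])
    ends = np.array([e.end_s for e in events])
    has_map = np.zeros(len(events), dtype=bool)
    has_iap = np.zeros(len(events), dtype=bool)
    participants: list[list[str]] = [[] for _ in events]
    for uid, cls in place_units.items():
        t = np.asarray(spikes_by_unit[uid], dtype=float)
        lo = np.searchsorted(t, starts, side="left")
        hi = np.searchsorted(t, ends, side="left")
        hit = hi > lo
        for i in np.flatnonzero(hit):
            participants[i].append(uid)
        if cls == "MAP":
            has_map |= hit
        else:
            has_iap |= hit
    for i, ev in enumerate(events):
        ev.participants = sorted(participants[i])
        if has_map[i] and has_iap[i]:
            ev.content_class = "joint"
        elif has_map[i]:
            ev.content_class = "MAP-only"
        elif has_iap[i]:
            ev.content_class = "IAP-only"
        else:
            ev.content_class = "neither"
    return events


def content_counts(
    events_or_counts: list[SwrEvent] | tuple[int, int, int],
) -> ContentCounts:
    """Observed class counts vs the independence expectation for joint events.

    With marginal participation probabilities estimated from the counts,
    the expected number of joint events is
    ``(n_map_only + n_joint) * (n_iap_only + n_joint) / n_total``; the
    observed joint/non-joint split is tested against it with a 1-d.f.
    goodness-of-fit chi-square.  'Neither' events are excluded.
    """
    if isinstance(events_or_counts, (tuple, list)) and len(events_or_counts) == 3 and all(
        isinstance(x, (int, np.integer)) for x in events_or_counts
    ):
        n_map, n_iap, n_joint = map(int, events_or_counts)
    else:
        classes = [e.content_class for e in events_or_counts]
        n_map = classes.count("MAP-only")
        n_iap = classes.count("IAP-only")
        n_joint = classes.count("joint")
    n_total = n_map + n_iap + n_joint
    if n_total == 0:
        raise ValueError("no classified events")
    expected = (n_map + n_joint) * (n_iap + n_joint) / n_total
    if expected in (0.0, float(n_total)):
        return ContentCounts(n_map, n_iap, n_joint, expected,
                             int(round(expected)), 0.0, float("nan"))
    chi2 = (n_joint - expected) ** 2 / expected + (
        (n_total - n_joint) - (n_total - expected)
    ) ** 2 / (n_total - expected)
    p = float(stats.chi2.sf(chi2, df=1))
    return ContentCounts(
        n_map, n_iap, n_joint, expected, int(np.floor(expected + 0.5)), float(chi2), p
    )


def participation_matrix(
    events: list[SwrEvent], spikes_by_unit: dict[str, np.ndarray]
) -> tuple[np.ndarray, list[str]]:
    """Binary event x unit participation matrix (spike count binarized)."""
    unit_ids = sorted(spikes_by_unit)
    starts = np.array([e.start_s for e in events])
    ends = np.array([e.end_s for e in events])
    mat = np.zeros((len(events), len(unit_ids)), dtype=bool)
    for j, uid in enumerate(unit_ids):
        t = np.asarray(spikes_by_unit[uid], dtype=float)
        mat[:, j] = np.searchsorted(t, ends, "left") > np.searchsorted(t, starts, "left")
    return mat, unit_ids


def coactivity_z(
    participation_a: np.ndarray,
    participation_b: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
    pair: tuple[str, str] = ("a", "b"),
) -> CoactivityResult:
    """Permutation z-score of a pair's joint ripple participation.

    The observed fraction of events where both units fire is compared to
    a null built by independently permuting each unit's participation
    vector across events ``n_permutations`` times; z is the observed
    fraction minus the null mean, divided by the null SD.  Pairs where a
    unit participates in no or every event are degenerate.
    """
    a = np.asarray(participation_a, dtype=bool)
    b = np.asarray(participation_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("participation vectors must be 1-D and equal length")
    n = a.size
    observed = float((a & b).mean())
    if a.sum() in (0, n) or b.sum() in (0, n):
        return CoactivityResult(pair, observed, float("nan"), float("nan"),
                                float("nan"), n_permutations, seed, degenerate=True)
    rng = np.random.default_rng(seed)
    A = rng.permuted(np.broadcast_to(a, (n_permutations, n)).copy(), axis=1)
    B = rng.permuted(np.broadcast_to(b, (n_permutations, n)).copy(), axis=1)
    null = (A & B).mean(axis=1)
    mu, sd = float(null.mean()), float(null.std())
    if sd == 0:
        return CoactivityResult(pair, observed, mu, sd, float("nan"),
                                n_permutations, seed, degenerate=True)
    return CoactivityResult(pair, observed, mu, sd, (observed - mu) / sd,
                            n_permutations, seed)


def pair_seed(global_seed: int, unit_a: str, unit_b: str) -> int:
    """Deterministic per-pair permutation seed, symmetric in the pair."""
    key = "|".join(sorted((unit_a, unit_b)))
    h = 2166136261
    for ch in key:  # FNV-1a, folded with the global seed
        h = ((h ^ ord(ch)) * 16777619) & 0xFFFFFFFF
    return int((h ^ (global_seed & 0xFFFFFFFF)) % (2**31 - 1))


def pair_eligibility(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    max_peak_lag_s: float = 3.3,
    bin_s: float = 0.010,
    window_s: float = 20.0,
    min_coincidences: int = 100,
) -> bool:
    """Pair eligible iff its cross-correlogram peak lies within +/- 3.3 s.

    Requires more than ``min_coincidences`` coincident events in the
    window; pairs active on widely separated timescales (peak beyond the
    half-bout duration) are excluded from coactivity comparisons.
    """
    cg = cross_correlogram(spikes_a, spikes_b, bin_s, window_s, min_coincidences)
    if not cg.eligible:
        return False
    return abs(cg.peak_lag_s) < max_peak_lag_s


def in_swr_latency(
    events: list[SwrEvent],
    place_class_by_unit: dict[str, str],
    spikes_by_unit: dict[str, np.ndarray],
    classes: tuple[str, ...] = ("joint",),
    truncate_to_s: float | None = None,
) -> dict[str, np.ndarray]:
    """Spike latencies from event start, pooled per place-cell class.

    By default only joint events are used, so IAP and MAP latencies come
    from the same events.  ``truncate_to_s`` restricts to spikes within a
    fixed time of event start as a duration-matched control.
    """
    out: dict[str, list[float]] = {"IAP": [], "MAP": []}
    for ev in events:
        if ev.content_class not in classes:
            continue
        end = ev.start_s + min(truncate_to_s, ev.duration_s) if truncate_to_s else ev.end_s
        for uid in ev.participants:
            cls = place_class_by_unit.get(uid)
            if cls not in ("IAP", "MAP"):
                continue
            t = np.asarray(spikes_by_unit[uid], dtype=float)
            sel = t[(t >= ev.start_s) & (t < end)]
            out[cls].extend(sel - ev.start_s)
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


def event_property_summary(events: list[SwrEvent]) -> dict:
    """Per-class duration and band-power distributions with pairwise tests.

    Returns per-class sorted duration and band-power arrays plus, for
    every class pair with at least two events each, Kolmogorov-Smirnov
    and Wilcoxon rank-sum statistics on both properties.
    """
    classes = sorted({e.content_class for e in events} - {"neither", "unassigned"})
    if len(classes) < 2:
        raise ValueError("need events from at least two content classes")
    by_class = {
        c: {
            "durations_s": np.sort([e.duration_s for e in events if e.content_class == c]),
            "band_power_z": np.sort(
                [e.band_power_z for e in events
                 if e.content_class == c and np.isfinite(e.band_power_z)]
            ),
        }
        for c in classes
    }
    tests = []
    for i, ca in enumerate(classes):
        for cb in classes[i + 1:]:
            for prop in ("durations_s", "band_power_z"):
                xa, xb = by_class[ca][prop], by_class[cb][prop]
                if len(xa) < 2 or len(xb) < 2:
                    continue
                ks = stats.ks_2samp(xa, xb)
                rs = stats.ranksums(xa, xb)
                tests.append(
                    {
                        "class_a": ca, "class_b": cb, "property": prop,
                        "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
                        "ranksum_stat": float(rs.statistic), "ranksum_p": float(rs.pvalue),
                    }
                )
    return {"classes": by_class, "tests": tests}
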