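"""PFC modulation during ripples.

For each PFC unit and ripple class the modulation index is
``I_SWR = (r_SWR - r_window) / r_window`` where ``r_SWR`` is the mean
rate inside events (over the class's mean event duration from each start)
and ``r_window`` is the mean rate in the 1 s window centered on event
starts.  Significance comes from a circular permutation test: spike times
in each event's window are circularly shifted by an independent uniform
offset, the PETH squared deviation from the control mean over the
mean-duration span is the statistic, and the p-value is the exceedance
fraction over 1000 permutations.  Units are then classified into the four
excitation/inhibition groups, with expected group sizes from the
8-combination accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ModulationResult",
    "modulation_index",
    "modulation_with_significance",
    "circular_permutation_test",
    "classify_group",
    "expected_group_counts",
    "group_binomial_test",
    "duration_matched_control",
    "label_permutation_control",
    "joint_modulation_regression",
    "COMBOS_PER_GROUP",
]

# number of significance combinations (out of 8 with any significance) per group
COMBOS_PER_GROUP = {
    "IAP-SWR+": 2,        # (+, n.s.) and (+, -)
    "MAP-SWR+": 2,        # (n.s., +) and (-, +)
    "IAP/MAP-SWR-": 3,    # (n.s., -), (-, n.s.), (-, -)
    "IAP-and-MAP-SWR+": 1,  # (+, +)
}


@dataclass
class ModulationResult:
    unit_id: str
    swr_class: str
    i_swr: float
    r_swr_hz: float
    r_window_hz: float
    p_value: float = float("nan")
    significance: str = "untested"   # excited | inhibited | n.s. | untested
    n_events: int = 0


def _event_arrays(events) -> tuple[np.ndarray, np.ndarray]:
    starts = np.array(
        [e.start_s if hasattr(e, "start_s") else e[0] for e in events], dtype=float
    )
    ends = np.array(
        [e.end_s if hasattr(e, "end_s") else e[1] for e in events], dtype=float
    )
    return starts, ends


def modulation_index(
    spike_times: np.ndarray,
    events,
    unit_id: str = "",
    swr_class: str = "",
    surround_window_s: float = 1.0,
    min_events: int = 10,
) -> ModulationResult:
    """SWR modulation index for one unit and one event class.

    ``r_SWR`` counts spikes in ``[start, start + mean duration)`` for every
    event; ``r_window`` counts spikes in the ``surround_window_s`` window
    centered on each event start.
    """
    t = np.asarray(spike_times, dtype=float)
    starts, ends = _event_arrays(events)
    if starts.size < min_events:
        raise ValueError(f"need at least {min_events} events, got {starts.size}")
    mean_dur = float(np.mean(ends - starts))
    half = surround_window_s / 2.0

    in_ev = (np.searchsorted(t, starts + mean_dur, "left")
             - np.searchsorted(t, starts, "left")).sum()
    in_win = (np.searchsorted(t, starts + half, "left")
              - np.searchsorted(t, starts - half, "left")).sum()
    r_swr = in_ev / (starts.size * mean_dur)
    r_window = in_win / (starts.size * surround_window_s)
    i_swr = (r_swr - r_window) / r_window if r_window > 0 else float("nan")
    return ModulationResult(unit_id, swr_class, float(i_swr), float(r_swr),
                            float(r_window), n_events=int(starts.size))


def circular_permutation_test(
    spike_times: np.ndarray,
    events,
    n_permutations: int = 1000,
    seed: int = 0,
    half_window_s: float = 0.5,
    bin_s: float = 0.010,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Circular-permutation significance of ripple-locked rate modulation.

    Spikes in each event's ``[-half_window_s, +half_window_s)`` window
    (relative to event start) form the observed PETH.  Each permutation
    circularly shifts every event's window spikes by an independent
    uniform offset, preserving per-event spike counts.  The statistic is
    the squared deviation from the control-mean PETH summed over the bins
    spanning the class's mean event duration; the p-value is the fraction
    of control deviations exceeding the observed one (floored at
    ``1/n_permutations``).

    Returns ``(p_value, observed_peth, control_mean_peth)`` with PETHs in
    spikes per event per bin.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    starts, ends = _event_arrays(events)
    n_ev = starts.size
    if n_ev == 0:
        raise ValueError("no events")
    window = 2 * half_window_s
    n_bins = int(round(window / bin_s))
    mean_dur = float(np.mean(ends - starts))

    # relative spike times in [-half, +half) per event
    lo = np.searchsorted(t, starts - half_window_s, "left")
    hi = np.searchsorted(t, starts + half_window_s, "left")
    lengths = hi - lo
    total = int(lengths.sum())
    if total == 0:
        raise ValueError("no spikes in any event window; test undefined")
    ev_of_spike = np.repeat(np.arange(n_ev), lengths)
    offsets0 = np.repeat(np.cumsum(lengths) - lengths, lengths)
    ii = np.arange(total) - offsets0 + np.repeat(lo, lengths)
    rel = t[ii] - starts[ev_of_spike] + half_window_s  # in [0, window)

    obs_bins = np.clip((rel / bin_s).astype(int), 0, n_bins - 1)
    observed = np.bincount(obs_bins, minlength=n_bins).astype(float) / n_ev

    rng = np.random.default_rng(seed)
    shifts = rng.uniform(0, window, size=(n_permutations, n_ev))
    shifted = (rel[None, :] + shifts[:, ev_of_spike]) % window
    perm_bins = np.clip((shifted / bin_s).astype(int), 0, n_bins - 1)
    flat = (perm_bins + n_bins * np.arange(n_permutations)[:, None]).ravel()
    controls = (
        np.bincount(flat, minlength=n_bins * n_permutations)
        .reshape(n_permutations, n_bins)
        .astype(float)
        / n_ev
    )
    control_mean = controls.mean(axis=0)

    # deviation over the mean-event-duration span after event start
    span = slice(n_bins // 2, min(n_bins // 2 + max(int(np.ceil(mean_dur / bin_s)), 1), n_bins))
    dev_obs = float(((observed - control_mean)[span] ** 2).sum())
    dev_ctrl = ((controls - control_mean)[:, span] ** 2).sum(axis=1)
    p = max(float((dev_ctrl > dev_obs).mean()), 1.0 / n_permutations)
    return p, observed, control_mean


def modulation_with_significance(
    spike_times: np.ndarray,
    events,
    unit_id: str = "",
    swr_class: str = "",
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_events: int = 10,
) -> ModulationResult:
    """Modulation index plus circular-permutation significance and direction."""
    res = modulation_index(spike_times, events, unit_id, swr_class, min_events=min_events)
    try:
        p, _, _ = circular_permutation_test(
            spike_times, events, n_permutations=n_permutations, seed=seed
        )
    except ValueError:
        res.p_value = float("nan")
        res.significance = "n.s."
        return res
    res.p_value = p
    if p < alpha and np.isfinite(res.i_swr):
        res.significance = "excited" if res.i_swr > 0 else "inhibited"
    else:
        res.significance = "n.s."
    return res


def classify_group(sig_iap: str, sig_map: str) -> str:
    """Four-group classification from the (IAP, MAP) significance pair.

    'excited'/'inhibited'/'n.s.' per class map to: excitation only during
    IAP ripples, only during MAP ripples, inhibition during either/both,
    excitation during both, or unclassified when neither is significant.
    """
    for s in (sig_iap, sig_map):
        if s not in ("excited", "inhibited", "n.s."):
            raise ValueError(f"invalid significance label {s!r}")
    if sig_iap == "excited" and sig_map == "excited":
        return "IAP-and-MAP-SWR+"
    if sig_iap == "excited":
        return "IAP-SWR+"
    if sig_map == "excited":
        return "MAP-SWR+"
    if "inhibited" in (sig_iap, sig_map):
        return "IAP/MAP-SWR-"
    return "unclassified"


def expected_group_counts(
    n_significant: int, combos_per_group: dict[str, int] | None = None
) -> dict[str, int]:
    """Expected group sizes if units spread evenly over the 8 significant combos.

    ``expected_g = round(combos_g * n / 8)`` with half rounded away from
    zero (e.g. 2 x 70 / 8 = 17.5 -> 18).
    """
    combos = combos_per_group or COMBOS_PER_GROUP
    return {g: int(np.floor(c * n_significant / 8 + 0.5)) for g, c in combos.items()}


def group_binomial_test(observed: int, n_significant: int, combos: int) -> float:
    """One-sided exact binomial tail toward the observed deviation.

    Success probability ``combos / 8``; the lower tail is used when the
    observed count falls below expectation, the upper tail otherwise.
    """
    if not 0 <= observed <= n_significant:
        raise ValueError("observed must lie in [0, n]")
    p0 = combos / 8.0
    if observed <= n_significant * p0:
        return float(stats.binom.cdf(observed, n_significant, p0))
    return float(stats.binom.sf(observed - 1, n_significant, p0))


def duration_matched_control(
    events_a, events_b, seed: int = 0, n_bins: int = 10
):
    """Resample both event sets so their duration distributions match.

    Durations are pooled into quantile bins; within each bin both groups
    are resampled with replacement to the smaller group's count.  Bins
    where one group is absent are dropped (best-effort match for disjoint
    supports).  Returns ``(resampled_a, resampled_b)``.
    """
    ev_a, ev_b = list(events_a), list(events_b)
    if not ev_a or not ev_b:
        raise ValueError("both event sets must be nonempty")
    dur_a = np.array([e.duration_s for e in ev_a])
    dur_b = np.array([e.duration_s for e in ev_b])
    pooled = np.concatenate([dur_a, dur_b])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    rng = np.random.default_rng(seed)
    out_a, out_b = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ia = np.flatnonzero((dur_a >= lo) & (dur_a < hi))
        ib = np.flatnonzero((dur_b >= lo) & (dur_b < hi))
        if ia.size == 0 or ib.size == 0:
            continue
        k = min(ia.size, ib.size)
        out_a.extend(ev_a[i] for i in rng.choice(ia, size=k, replace=True))
        out_b.extend(ev_b[i] for i in rng.choice(ib, size=k, replace=True))
    out_a.sort(key=lambda e: e.start_s)
    out_b.sort(key=lambda e: e.start_s)
    return out_a, out_b


def label_permutation_control(
    spike_times: np.ndarray,
    events_by_class: dict[str, list],
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Shuffle event class labels and recompute the index difference.

    The observed ``|I_a - I_b|`` between the two classes is compared with
    the distribution obtained by permuting class labels across the pooled
    events; class-selective units exceed the shuffled differences.
    """
    classes = sorted(events_by_class)
    if len(classes) != 2:
        raise ValueError("label permutation control expects exactly two classes")
    ca, cb = classes
    pooled = list(events_by_class[ca]) + list(events_by_class[cb])
    na = len(events_by_class[ca])

    def index_for(events) -> float:
        return modulation_index(spike_times, events, min_events=1).i_swr

    observed = abs(index_for(events_by_class[ca]) - index_for(events_by_class[cb]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    idx = np.arange(len(pooled))
    for k in range(n_permutations):
        rng.shuffle(idx)
        ga = [pooled[i] for i in idx[:na]]
        gb = [pooled[i] for i in idx[na:]]
        null[k] = abs(index_for(ga) - index_for(gb))
    p = float((null >= observed).mean())
    return {"observed_diff": observed, "null": null, "p_value": p}


def joint_modulation_regression(
    i_joint: np.ndarray, i_map: np.ndarray, i_iap: np.ndarray
) -> dict:
    """Least squares of joint-ripple indices on (MAP, IAP) indices.

    Fits ``I_joint ~ b0 + b1 I_map + b2 I_iap`` and reports coefficients
    and R-squared.
    """
    yj = np.asarray(i_joint, dtype=float)
    xm = np.asarray(i_map, dtype=float)
    xi = np.asarray(i_iap, dtype=float)
    ok = np.isfinite(yj) & np.isfinite(xm) & np.isfinite(xi)
    yj, xm, xi = yj[ok], xm[ok], xi[ok]
    if yj.size < 3:
        raise ValueError("need at least 3 units with all three indices")
    X = np.column_stack([np.ones_like(xm), xm, xi])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
    resid = yj - X @ beta
    ss_tot = float(((yj - yj.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return {"coef": beta, "r_squared": r2, "n": int(yj.size)}
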