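"""Synthetic session generator with ground truth.

Emulates the statistical structure the analysis pipeline assumes: a rat
alternating ~6.6 s bouts of movement (straight runs between reward wells)
and immobility (reward consumption at a well); CA1 units that are either
movement-associated place cells (MAPs, 2-D Gaussian place fields gated to
speed > 4 cm/s, theta-modulated) or immobility-associated place cells
(IAPs, Poisson firing while immobile at a single home well); ripple-band
bursts injected into pink-noise LFP during immobility with labeled spike
content (MAP-only / IAP-only / joint); and PFC units with behavior-locked
rates and class-specific multiplicative gain during ripples.

Every generator takes an explicit seed; the same seed reproduces the
output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    LfpBundle,
    PositionTrace,
    Session,
    SpikeTrain,
    WellEvent,
    WellGeometry,
)
from .ripples import ripple_bandpass

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SwrTruthEvent",
    "generate_behavior",
    "generate_ca1_units",
    "generate_lfp_with_swrs",
    "generate_pfc_units",
    "generate_session",
]

# (gain during MAP-only, IAP-only, joint ripples), behavioral tuning
PFC_GROUP_PROFILES = {
    "IAP-locked": {"gains": {"MAP-only": 1.0, "IAP-only": 4.0, "joint": 4.0},
                   "behavior": "immobility-onset"},
    "MAP-locked": {"gains": {"MAP-only": 4.0, "IAP-only": 1.0, "joint": 4.0},
                   "behavior": "movement"},
    "inhibited": {"gains": {"MAP-only": 0.15, "IAP-only": 0.15, "joint": 0.15},
                  "behavior": "flat"},
    "flat": {"gains": {"MAP-only": 1.0, "IAP-only": 1.0, "joint": 1.0},
             "behavior": "flat"},
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session.

    Defaults reproduce the task statistics the analysis assumes: four
    reward wells, bouts alternating every ~6.6 s, a 150-250 Hz ripple
    carrier at 200 Hz, and content-class probabilities 0.67/0.26/0.07
    (MAP-only / IAP-only / joint).
    """

    session_length_s: float = 1800.0
    n_wells: int = 4
    arena_cm: float = 100.0
    well_margin_cm: float = 10.0
    well_radius_cm: float = 10.0
    position_rate_hz: float = 30.0
    mean_bout_s: float = 6.6
    bout_sd_s: float = 1.0
    bout_min_s: float = 3.0
    bout_max_s: float = 12.0
    speed_ramp_s: float = 0.3
    movement_pad_s: float = 0.2   # stationary margin inside each movement bout
    immobility_jitter_cm: float = 0.05

    n_map: int = 30
    n_iap: int = 10
    n_interneuron: int = 2
    field_peak_hz: float = 20.0
    field_sigma_cm: float = 8.0
    iap_rate_hz: float = 8.0
    theta_freq_hz: float = 8.0
    theta_depth: float = 0.8
    pyramidal_width_ms: float = 0.6
    interneuron_width_ms: float = 0.25
    interneuron_rate_hz: float = 15.0

    lfp_sample_rate_hz: float = 1500.0
    n_channels: int = 4
    lfp_noise_uv: float = 50.0
    swr_rate_hz: float = 0.4
    swr_duration_mu: float = float(np.log(0.1))
    swr_duration_sigma: float = 0.25
    swr_duration_min_s: float = 0.05
    swr_duration_max_s: float = 0.4
    ripple_freq_hz: float = 200.0
    ripple_snr: float = 5.0
    class_probs: tuple[float, float, float] = (0.67, 0.26, 0.07)  # MAP-only, IAP-only, joint
    participation_prob: float = 0.15
    spikes_per_participant_mean: float = 2.0
    swr_silence_margin_s: float = 0.05  # background pyramidal silence around events
    joint_iap_early_s: float = 0.0
    class_duration_scale: dict = field(
        default_factory=lambda: {"MAP-only": 1.0, "IAP-only": 0.8, "joint": 1.2})
    class_amplitude_scale: dict = field(
        default_factory=lambda: {"MAP-only": 1.0, "IAP-only": 0.85, "joint": 1.15})

    n_pfc: int = 20
    pfc_group_counts: dict = field(
        default_factory=lambda: {"IAP-locked": 6, "MAP-locked": 6,
                                 "inhibited": 5, "flat": 3})
    pfc_baseline_hz: float = 5.0
    pfc_behavior_gain: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_probs, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or not np.isclose(p.sum(), 1.0):
            raise ValueError("class_probs must be probabilities summing to 1")
        if self.n_map + self.n_iap == 0:
            raise ValueError("need at least one CA1 place unit (n_map + n_iap > 0)")
        if self.ripple_snr <= 0:
            raise ValueError("ripple_snr must be > 0")
        for name in ("swr_rate_hz", "iap_rate_hz", "field_peak_hz", "pfc_baseline_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if sum(self.pfc_group_counts.values()) != self.n_pfc:
            raise ValueError("pfc_group_counts must sum to n_pfc")

    def well_positions(self) -> np.ndarray:
        m, a = self.well_margin_cm, self.arena_cm
        corners = np.array([[m, m], [a - m, m], [a - m, a - m], [m, a - m]], dtype=float)
        if self.n_wells <= 4:
            return corners[: self.n_wells]
        # extra wells on a circle inside the arena
        k = self.n_wells - 4
        ang = 2 * np.pi * np.arange(k) / k
        r = (a / 2 - m) * 0.5
        extra = np.column_stack([a / 2 + r * np.cos(ang), a / 2 + r * np.sin(ang)])
        return np.vstack([corners, extra])


@dataclass
class SwrTruthEvent:
    start_s: float
    end_s: float
    content_class: str              # MAP-only | IAP-only | joint
    participants: list[str]
    amplitude_scale: float = 1.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class GroundTruth:
    unit_labels: dict[str, dict]
    swr_truth: list[SwrTruthEvent]
    bout_schedule: list[tuple]      # (state, start_s, end_s, well_id or (from, to))

    def units_of_type(self, kind: str) -> list[str]:
        return [u for u, lab in self.unit_labels.items() if lab["type"] == kind]


# ---------------------------------------------------------------------------
# behavior


def _draw_bout(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    d = rng.normal(cfg.mean_bout_s, cfg.bout_sd_s)
    return float(np.clip(d, cfg.bout_min_s, cfg.bout_max_s))


def generate_behavior(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[PositionTrace, list[WellGeometry], list[WellEvent], list[tuple]]:
    """Simulate the alternating well-visit trajectory.

    Immobility bouts sit at a well with sub-cm positional jitter; movement
    bouts follow the straight path to a uniformly chosen other well with a
    trapezoidal speed profile (short ramps, cruise well above 10 cm/s).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    wp = cfg.well_positions()
    wells = [
        WellGeometry(f"w{i}", float(wp[i, 0]), float(wp[i, 1]), cfg.well_radius_cm)
        for i in range(cfg.n_wells)
    ]

    if cfg.session_length_s < cfg.bout_max_s + cfg.bout_min_s:
        raise ValueError("session too short for a full immobility+movement cycle")

    dt = 1.0 / cfg.position_rate_hz
    n = int(np.floor(cfg.session_length_s / dt)) + 1
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    true_speed = np.zeros(n)

    schedule: list[tuple] = []
    events: list[WellEvent] = []
    cur_well = int(rng.integers(cfg.n_wells))
    t_cur = 0.0
    state = "immobility"
    events.append(WellEvent(0.0, wells[cur_well].well_id, "entry"))
    while t_cur < cfg.session_length_s:
        if state == "immobility":
            dur = _draw_bout(rng, cfg)
            t_end = min(t_cur + dur, cfg.session_length_s)
            i0, i1 = int(np.ceil(t_cur / dt)), int(np.floor(t_end / dt))
            idx = slice(i0, min(i1 + 1, n))
            m = x[idx].size
            x[idx] = wp[cur_well, 0] + rng.normal(0, cfg.immobility_jitter_cm, m)
            y[idx] = wp[cur_well, 1] + rng.normal(0, cfg.immobility_jitter_cm, m)
            schedule.append(("immobility", t_cur, t_end, wells[cur_well].well_id))
            if t_end < cfg.session_length_s:
                events.append(WellEvent(t_end, wells[cur_well].well_id, "exit"))
            t_cur, state = t_end, "movement"
        else:
            nxt = int(rng.choice([w for w in range(cfg.n_wells) if w != cur_well]))
            p0, p1 = wp[cur_well], wp[nxt]
            dist = float(np.hypot(*(p1 - p0)))
            dur = _draw_bout(rng, cfg)
            t_end = min(t_cur + dur, cfg.session_length_s)
            pad = min(cfg.movement_pad_s, (t_end - t_cur) / 6)
            dur_eff = t_end - t_cur - 2 * pad  # stationary pad at both ends
            ramp = min(cfg.speed_ramp_s, dur_eff / 3)
            peak = dist / max(dur_eff - ramp, 1e-6)  # trapezoid area = peak*(T - ramp)
            i0, i1 = int(np.ceil(t_cur / dt)), int(np.floor(t_end / dt))
            idx = np.arange(i0, min(i1 + 1, n))
            tau = np.clip(t[idx] - t_cur - pad, 0.0, dur_eff)
            sp = np.where(
                tau < ramp, peak * tau / ramp,
                np.where(tau > dur_eff - ramp, peak * (dur_eff - tau) / ramp, peak),
            )
            sp = np.clip(sp, 0, peak)
            # distance along the path: integral of the trapezoid profile
            s = np.where(
                tau < ramp, 0.5 * peak * tau**2 / ramp,
                np.where(
                    tau > dur_eff - ramp,
                    dist - 0.5 * peak * np.maximum(dur_eff - tau, 0) ** 2 / ramp,
                    0.5 * peak * ramp + peak * (tau - ramp),
                ),
            )
            frac = np.clip(s / dist, 0, 1)
            x[idx] = p0[0] + frac * (p1[0] - p0[0])
            y[idx] = p0[1] + frac * (p1[1] - p0[1])
            true_speed[idx] = sp
            schedule.append(
                ("movement", t_cur, t_end, (wells[cur_well].well_id, wells[nxt].well_id))
            )
            if t_end < cfg.session_length_s:
                events.append(WellEvent(t_end, wells[nxt].well_id, "entry"))
            cur_well, t_cur, state = nxt, t_end, "immobility"

    position = PositionTrace(t, x, y, np.maximum(true_speed, 0.0))
    return position, wells, events, schedule


# ---------------------------------------------------------------------------
# CA1 units


def _thinned_poisson(
    rng: np.random.Generator,
    intervals: np.ndarray,
    max_rate: float,
    rate_fn,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes on a union of intervals, by thinning."""
    out = []
    for lo, hi in intervals:
        span = hi - lo
        if span <= 0 or max_rate <= 0:
            continue
        n_cand = rng.poisson(max_rate * span)
        if n_cand == 0:
            continue
        cand = np.sort(rng.uniform(lo, hi, n_cand))
        accept = rng.uniform(0, max_rate, n_cand) < rate_fn(cand)
        out.append(cand[accept])
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def generate_ca1_units(
    cfg: GeneratorConfig,
    position: PositionTrace,
    wells: list[WellGeometry],
    schedule: list[tuple],
    seed: int | None = None,
) -> tuple[list[SpikeTrain], dict[str, dict]]:
    """Generate MAP, IAP and interneuron spike trains from the trajectory.

    MAPs: inhomogeneous Poisson with a 2-D Gaussian place field centered
    on a random inter-well path, gated to speed > 4 cm/s and theta
    modulated.  IAPs: Poisson at ``iap_rate_hz`` while immobile at their
    home well, silent elsewhere.  Interneurons: tonic Poisson with narrow
    spike width.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    wp = cfg.well_positions()
    t, xs, ys = position.time_s, position.x_cm, position.y_cm
    speed = position.speed_cm_s
    move_iv = np.array(
        [(s, e) for st, s, e, _ in schedule if st == "movement"], dtype=float
    ).reshape(-1, 2)

    units: list[SpikeTrain] = []
    labels: dict[str, dict] = {}
    edges = [(i, j) for i in range(cfg.n_wells) for j in range(i + 1, cfg.n_wells)]

    for k in range(cfg.n_map):
        i, j = edges[int(rng.integers(len(edges)))]
        u = rng.uniform(0.3, 0.7)
        center = wp[i] + u * (wp[j] - wp[i])
        phase = rng.uniform(0, 2 * np.pi)

        def rate_fn(times, center=center, phase=phase):
            px = np.interp(times, t, xs)
            py = np.interp(times, t, ys)
            sp = np.interp(times, t, speed)
            d2 = (px - center[0]) ** 2 + (py - center[1]) ** 2
            base = cfg.field_peak_hz * np.exp(-d2 / (2 * cfg.field_sigma_cm**2))
            theta = 1 + cfg.theta_depth * np.sin(2 * np.pi * cfg.theta_freq_hz * times + phase)
            return np.where(sp > 4.0, base * theta, 0.0)

        max_rate = cfg.field_peak_hz * (1 + cfg.theta_depth)
        spikes = _thinned_poisson(rng, move_iv, max_rate, rate_fn)
        uid = f"map{k:03d}"
        units.append(_make_train(uid, "CA1", spikes, cfg.pyramidal_width_ms, rng))
        labels[uid] = {"type": "MAP", "field_center_cm": [float(center[0]), float(center[1])]}

    for k in range(cfg.n_iap):
        home = k % cfg.n_wells
        home_id = wells[home].well_id
        home_iv = np.array(
            [(s, e) for st, s, e, w in schedule if st == "immobility" and w == home_id],
            dtype=float,
        ).reshape(-1, 2)
        spikes = _thinned_poisson(
            rng, home_iv, cfg.iap_rate_hz, lambda c: np.full(c.size, cfg.iap_rate_hz)
        )
        uid = f"iap{k:03d}"
        units.append(_make_train(uid, "CA1", spikes, cfg.pyramidal_width_ms, rng))
        labels[uid] = {"type": "IAP", "well_id": home_id}

    whole = np.array([[t[0], t[-1]]])
    for k in range(cfg.n_interneuron):
        spikes = _thinned_poisson(
            rng, whole, cfg.interneuron_rate_hz,
            lambda c: np.full(c.size, cfg.interneuron_rate_hz),
        )
        uid = f"int{k:03d}"
        units.append(_make_train(uid, "CA1", spikes, cfg.interneuron_width_ms, rng))
        labels[uid] = {"type": "INT"}

    return units, labels


def _make_train(
    uid: str, region: str, spikes: np.ndarray, width_ms: float, rng: np.random.Generator
) -> SpikeTrain:
    spikes = np.unique(np.sort(spikes))
    if spikes.size == 0:
        # keep the train valid with a single marker spike; practically unreachable
        spikes = np.array([rng.uniform(0, 1)])
    return SpikeTrain(uid, region, spikes, width_ms)


# ---------------------------------------------------------------------------
# LFP with injected ripples


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** -0.5
    out = np.fft.irfft(spec, n)
    return out * (sd / out.std())


def generate_lfp_with_swrs(
    cfg: GeneratorConfig,
    schedule: list[tuple],
    ca1_units: list[SpikeTrain],
    labels: dict[str, dict],
    seed: int | None = None,
) -> tuple[LfpBundle, list[SwrTruthEvent], list[SpikeTrain]]:
    """Pink-noise LFP with ripple bursts injected during immobility.

    Each burst is a sinusoid at ``ripple_freq_hz`` under a raised-cosine
    envelope, added to every channel with amplitude ``ripple_snr`` times
    that channel's ripple-band noise SD.  Bursts get a content class drawn
    from ``class_probs`` and participant spikes (Bernoulli participation,
    uniform spike times within the event) appended to the unit trains.
    Returns the LFP, the ground-truth event list and the updated trains.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    fs = cfg.lfp_sample_rate_hz
    n = int(round(cfg.session_length_s * fs))
    lfp = np.column_stack(
        [_pink_noise(rng, n, cfg.lfp_noise_uv) for _ in range(cfg.n_channels)]
    )
    # in-band noise SD per channel sets the ripple amplitude scale
    band_sd = ripple_bandpass(lfp, fs).std(axis=0)

    imm_iv = [(s, e, w) for st, s, e, w in schedule if st == "immobility"]
    map_ids = [u for u, lab in labels.items() if lab["type"] == "MAP"]
    iap_ids = [u for u, lab in labels.items() if lab["type"] == "IAP"]
    class_names = ["MAP-only", "IAP-only", "joint"]
    probs = np.asarray(cfg.class_probs, dtype=float)

    truth: list[SwrTruthEvent] = []
    extra_spikes: dict[str, list[np.ndarray]] = {u.unit_id: [] for u in ca1_units}
    t_axis = np.arange(n) / fs
    last_end = -1.0
    for lo, hi, _ in imm_iv:
        span = hi - lo - 0.3
        if span <= 0 or cfg.swr_rate_hz <= 0:
            continue
        n_ev = rng.poisson(cfg.swr_rate_hz * span)
        starts = np.sort(rng.uniform(lo + 0.1, hi - 0.2, n_ev))
        for s0 in starts:
            cls = class_names[int(rng.choice(3, p=probs))]
            dur = float(
                np.clip(
                    rng.lognormal(cfg.swr_duration_mu, cfg.swr_duration_sigma)
                    * cfg.class_duration_scale.get(cls, 1.0),
                    cfg.swr_duration_min_s,
                    cfg.swr_duration_max_s,
                )
            )
            if s0 < last_end + 0.25 or s0 + dur > hi - 0.1:
                continue
            last_end = s0 + dur
            amp_scale = float(cfg.class_amplitude_scale.get(cls, 1.0))
            i0, i1 = int(round(s0 * fs)), int(round((s0 + dur) * fs))
            tau = t_axis[i0:i1] - s0
            env = 0.5 * (1 - np.cos(2 * np.pi * tau / dur))
            carrier = np.sin(2 * np.pi * cfg.ripple_freq_hz * tau + rng.uniform(0, 2 * np.pi))
            for ch in range(cfg.n_channels):
                lfp[i0:i1, ch] += cfg.ripple_snr * amp_scale * band_sd[ch] * env * carrier

            participants = _draw_participants(rng, cls, map_ids, iap_ids, cfg)
            for uid in participants:
                n_sp = 1 + rng.poisson(cfg.spikes_per_participant_mean - 1)
                if cls == "joint" and uid in iap_ids and cfg.joint_iap_early_s > 0:
                    hi_t = max(dur - cfg.joint_iap_early_s, 0.25 * dur)
                    times = s0 + rng.uniform(0, hi_t, n_sp)
                else:
                    times = s0 + rng.uniform(0, dur, n_sp)
                extra_spikes[uid].append(times)
            truth.append(SwrTruthEvent(float(s0), float(s0 + dur), cls,
                                       sorted(participants), amp_scale))

    # Reactivation is selective: non-injected pyramidal spikes are removed in
    # a small margin around every event so an event's participants are exactly
    # the drawn ones even after detected boundaries overshoot the truth edges.
    margin = cfg.swr_silence_margin_s
    silent = np.array(
        [[ev.start_s - margin, ev.end_s + margin] for ev in truth], dtype=float
    ).reshape(-1, 2)
    pyramidal = set(map_ids) | set(iap_ids)
    updated = []
    for u in ca1_units:
        base_t = u.spike_times_s
        if u.unit_id in pyramidal and silent.size:
            base_t = base_t[~_in_intervals(base_t, silent)]
        extras = extra_spikes.get(u.unit_id, [])
        allt = np.unique(np.concatenate([base_t, *extras])) if extras else base_t
        if allt.size == 0:
            allt = u.spike_times_s[:1]  # keep the train non-empty
        if allt.size != u.spike_times_s.size or extras:
            updated.append(SpikeTrain(u.unit_id, u.region, allt, u.spike_width_ms))
        else:
            updated.append(u)

    bundle = LfpBundle(fs, [f"ch{i}" for i in range(cfg.n_channels)], lfp, 0.0)
    return bundle, truth, updated


def _draw_participants(
    rng: np.random.Generator,
    cls: str,
    map_ids: list[str],
    iap_ids: list[str],
    cfg: GeneratorConfig,
) -> list[str]:
    chosen: list[str] = []
    pools = {"MAP-only": [map_ids], "IAP-only": [iap_ids], "joint": [map_ids, iap_ids]}[cls]
    for pool in pools:
        if not pool:
            continue
        take = [u for u in pool if rng.random() < cfg.participation_prob]
        if not take:
            take = [pool[int(rng.integers(len(pool)))]]
        chosen.extend(take)
    return chosen


# ---------------------------------------------------------------------------
# PFC units


def generate_pfc_units(
    cfg: GeneratorConfig,
    schedule: list[tuple],
    swr_truth: list[SwrTruthEvent],
    seed: int | None = None,
) -> tuple[list[SpikeTrain], dict[str, dict]]:
    """PFC spike trains: baseline Poisson x behavior gain x ripple-class gain.

    Group profiles (see ``PFC_GROUP_PROFILES``): units excited selectively
    during IAP-only or MAP-only ripples, units inhibited during all
    ripples, and unmodulated units.  Behavior tuning boosts rate during
    movement or in the 2 s after immobility onset, matching the group's
    ripple preference.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 3)
    move_iv = np.array(
        [(s, e) for st, s, e, _ in schedule if st == "movement"], dtype=float
    ).reshape(-1, 2)
    imm_onsets = np.array(
        [(s, min(s + 2.0, e)) for st, s, e, _ in schedule if st == "immobility"],
        dtype=float,
    ).reshape(-1, 2)
    ev_start = np.array([ev.start_s for ev in swr_truth])
    ev_end = np.array([ev.end_s for ev in swr_truth])

    session_end = max(e for _, _, e, _ in schedule)
    whole = np.array([[0.0, session_end]])

    units: list[SpikeTrain] = []
    labels: dict[str, dict] = {}
    k = 0
    for group, count in cfg.pfc_group_counts.items():
        profile = PFC_GROUP_PROFILES[group]
        gains = profile["gains"]
        ev_gain = np.array([gains[ev.content_class] for ev in swr_truth]) if swr_truth else np.empty(0)
        for _ in range(count):
            def rate_fn(times, ev_gain=ev_gain, behavior=profile["behavior"]):
                r = np.full(times.size, cfg.pfc_baseline_hz)
                if behavior == "movement":
                    r *= np.where(_in_intervals(times, move_iv), cfg.pfc_behavior_gain, 1.0)
                elif behavior == "immobility-onset":
                    r *= np.where(_in_intervals(times, imm_onsets), cfg.pfc_behavior_gain, 1.0)
                if ev_start.size:
                    idx = np.searchsorted(ev_start, times, side="right") - 1
                    ok = (idx >= 0) & (times < ev_end[np.maximum(idx, 0)])
                    g = np.ones(times.size)
                    g[ok] = ev_gain[idx[ok]]
                    r *= g
                return r

            max_rate = cfg.pfc_baseline_hz * cfg.pfc_behavior_gain * max(
                max(gains.values()), 1.0
            )
            spikes = _thinned_poisson(rng, whole, max_rate, rate_fn)
            uid = f"pfc{k:03d}"
            units.append(_make_train(uid, "PFC", spikes, cfg.pyramidal_width_ms, rng))
            labels[uid] = {"type": "PFC", "group": group, "gain_by_class": dict(gains)}
            k += 1
    return units, labels


def _in_intervals(times: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    if intervals.size == 0:
        return np.zeros(times.size, dtype=bool)
    idx = np.searchsorted(intervals[:, 0], times, side="right") - 1
    ok = idx >= 0
    out = np.zeros(times.size, dtype=bool)
    out[ok] = times[ok] < intervals[idx[ok], 1]
    return out


# ---------------------------------------------------------------------------
# full session


def generate_session(
    cfg: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[Session, GroundTruth]:
    """Compose behavior, CA1 units, LFP-with-ripples and PFC units."""
    cfg = cfg or GeneratorConfig()
    base = cfg.seed if seed is None else seed
    position, wells, well_events, schedule = generate_behavior(cfg, base)
    ca1_units, ca1_labels = generate_ca1_units(cfg, position, wells, schedule, base)
    lfp, truth, ca1_units = generate_lfp_with_swrs(cfg, schedule, ca1_units, ca1_labels, base)
    pfc_units, pfc_labels = generate_pfc_units(cfg, schedule, truth, base)

    session = Session(
        position=position,
        units=ca1_units + pfc_units,
        lfp=lfp,
        wells=wells,
        well_events=well_events,
        metadata={"generator_seed": int(base), "synthetic": True},
    )
    ground_truth = GroundTruth(
        unit_labels={**ca1_labels, **pfc_labels},
        swr_truth=truth,
        bout_schedule=schedule,
    )
    return session, ground_truth
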