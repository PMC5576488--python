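"""Synthetic session generator: determinism and structural post-conditions."""

from __future__ import annotations

import numpy as np
import pytest

from swrpipe.model import spikes_in_intervals
from swrpipe.synth import GeneratorConfig, generate_behavior, generate_session
from conftest import small_generator_config


def test_same_seed_reproduces_session(small_session):
    session, truth = small_session
    again, truth2 = generate_session(small_generator_config(), 5)
    np.testing.assert_array_equal(session.position.x_cm, again.position.x_cm)
    np.testing.assert_array_equal(session.lfp.samples, again.lfp.samples)
    assert [u.unit_id for u in session.units] == [u.unit_id for u in again.units]
    for ua, ub in zip(session.units, again.units):
        np.testing.assert_array_equal(ua.spike_times_s, ub.spike_times_s)
    assert [(e.start_s, e.end_s, e.content_class) for e in truth.swr_truth] == [
        (e.start_s, e.end_s, e.content_class) for e in truth2.swr_truth
    ]


def test_different_seed_differs():
    a, _ = generate_session(small_generator_config(), 5)
    b, _ = generate_session(small_generator_config(), 6)
    assert not np.array_equal(a.lfp.samples, b.lfp.samples)


def test_unit_inventory_matches_config(small_session):
    session, truth = small_session
    cfg = small_generator_config()
    types = [lab["type"] for lab in truth.unit_labels.values()]
    assert types.count("MAP") == cfg.n_map
    assert types.count("IAP") == cfg.n_iap
    assert types.count("INT") == cfg.n_interneuron
    assert types.count("PFC") == cfg.n_pfc
    assert len(session.units) == len(truth.unit_labels)
    groups = [lab["group"] for lab in truth.unit_labels.values()
              if lab["type"] == "PFC"]
    for g, n in cfg.pfc_group_counts.items():
        assert groups.count(g) == n


def test_spike_trains_strictly_increasing_and_nonempty(small_session):
    session, _ = small_session
    for u in session.units:
        assert u.n_spikes >= 1
        if u.n_spikes > 1:
            assert np.all(np.diff(u.spike_times_s) > 0)


def test_bout_schedule_tiles_session(small_session):
    session, truth = small_session
    sched = truth.bout_schedule
    assert sched[0][1] == pytest.approx(0.0)
    assert sched[-1][2] == pytest.approx(small_generator_config().session_length_s)
    for (sa, a0, a1, _), (sb, b0, b1, _) in zip(sched, sched[1:]):
        assert a1 == pytest.approx(b0)
        assert sa != sb


def test_truth_events_inside_immobility(small_session):
    _, truth = small_session
    imm = [(s, e) for st, s, e, _ in truth.bout_schedule if st == "immobility"]
    for ev in truth.swr_truth:
        assert any(lo <= ev.start_s and ev.end_s <= hi for lo, hi in imm)


def test_truth_event_durations_and_gaps(small_session):
    _, truth = small_session
    cfg = small_generator_config()
    evs = sorted(truth.swr_truth, key=lambda e: e.start_s)
    for ev in evs:
        assert cfg.swr_duration_min_s <= ev.duration_s <= cfg.swr_duration_max_s * 1.3
    for ea, eb in zip(evs, evs[1:]):
        assert eb.start_s - ea.end_s >= 0.25 - 1e-9


def test_every_event_has_consistent_participants(small_session):
    _, truth = small_session
    iaps = set(truth.units_of_type("IAP"))
    maps = set(truth.units_of_type("MAP"))
    for ev in truth.swr_truth:
        assert len(ev.participants) >= 1
        has_map = any(u in maps for u in ev.participants)
        has_iap = any(u in iaps for u in ev.participants)
        expected = {"MAP-only": (True, False), "IAP-only": (False, True),
                    "joint": (True, True)}[ev.content_class]
        assert (has_map, has_iap) == expected


def test_participant_spikes_present_and_nonparticipants_silent(small_session):
    """The spike data matches the truth labels exactly inside event windows."""
    session, truth = small_session
    cfg = small_generator_config()
    place_units = set(truth.units_of_type("MAP")) | set(truth.units_of_type("IAP"))
    spikes = {u.unit_id: u.spike_times_s for u in session.units}
    for ev in truth.swr_truth:
        window = np.array([[ev.start_s, ev.end_s]])
        silent_window = np.array([
            [ev.start_s - cfg.swr_silence_margin_s,
             ev.end_s + cfg.swr_silence_margin_s]
        ])
        for uid in place_units:
            inside = spikes_in_intervals(spikes[uid], window).sum()
            near = spikes_in_intervals(spikes[uid], silent_window).sum()
            if uid in ev.participants:
                assert inside >= 1
            else:
                assert near == 0


def test_lfp_has_ripple_energy_at_events(small_session):
    from swrpipe.ripples import ripple_bandpass

    session, truth = small_session
    filt = ripple_bandpass(session.lfp)
    env = np.abs(filt).mean(axis=1)
    fs = session.lfp.sample_rate_hz
    baseline = np.median(env)
    for ev in truth.swr_truth[:10]:
        i0, i1 = int(ev.start_s * fs), int(ev.end_s * fs)
        assert env[i0:i1].max() > 3 * baseline


def test_mean_bout_duration_at_scale():
    """Over ~1000 bouts the mean bout duration is close to the configured mean."""
    cfg = GeneratorConfig(session_length_s=6600.0)
    _, _, _, schedule = generate_behavior(cfg, 2)
    durs = [e - s for _, s, e, _ in schedule[1:-1]]  # drop truncated edge bouts
    assert len(durs) > 800
    assert np.mean(durs) == pytest.approx(cfg.mean_bout_s, rel=0.05)


def test_class_probabilities_respected():
    cfg = GeneratorConfig(session_length_s=3600.0, n_map=8, n_iap=4, n_interneuron=1,
                          n_pfc=4, pfc_group_counts={"IAP-locked": 1, "MAP-locked": 1,
                                                     "inhibited": 1, "flat": 1})
    _, truth = generate_session(cfg, 9)
    classes = [e.content_class for e in truth.swr_truth]
    n = len(classes)
    assert n > 300
    for cls, p in zip(("MAP-only", "IAP-only", "joint"), cfg.class_probs):
        frac = classes.count(cls) / n
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 4 * sd + 1e-9, (cls, frac, p)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(class_probs=(0.5, 0.5, 0.5)).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(n_map=0, n_iap=0).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(ripple_snr=0.0).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(n_pfc=3).validate()


def test_session_metadata_marks_synthetic(small_session):
    session, _ = small_session
    assert session.metadata["synthetic"] is True
    assert session.metadata["generator_seed"] == 5
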