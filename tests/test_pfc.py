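"""PFC ripple-modulation index, permutation test and group accounting."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from swrpipe.pfc import (
    COMBOS_PER_GROUP,
    circular_permutation_test,
    classify_group,
    duration_matched_control,
    expected_group_counts,
    group_binomial_test,
    joint_modulation_regression,
    label_permutation_control,
    modulation_index,
    modulation_with_significance,
)
from swrpipe.ripples import SwrEvent


def _regular_events(n=100, start=5.0, gap=4.0, dur=0.1):
    return [(start + k * gap, start + k * gap + dur) for k in range(n)]


def test_modulation_index_counting_oracle():
    events = _regular_events(n=20)
    # 3 spikes inside each event, 1 extra in each surround window
    spikes = []
    for s, e in events:
        spikes.extend([s + 0.01, s + 0.05, s + 0.09, s - 0.3])
    spikes = np.sort(spikes)
    res = modulation_index(spikes, events)
    # r_swr = 3 / 0.1 = 30 Hz; r_window = 4 / 1 s = 4 Hz
    assert res.r_swr_hz == pytest.approx(30.0)
    assert res.r_window_hz == pytest.approx(4.0)
    assert res.i_swr == pytest.approx((30 - 4) / 4)
    assert res.n_events == 20


def test_modulation_index_uses_mean_duration():
    # mixed durations: r_swr counts spikes within the mean duration of start
    events = [(0.0, 0.05), (10.0, 0.15 + 10.0)]  # durations 0.05 and 0.15
    spikes = np.array([0.08, 10.08])  # both inside [start, start+0.1)
    res = modulation_index(spikes, events, min_events=1)
    assert res.r_swr_hz == pytest.approx(2 / (2 * 0.1))


def test_modulation_index_min_events():
    with pytest.raises(ValueError):
        modulation_index(np.array([1.0]), _regular_events(n=5), min_events=10)


def test_circular_permutation_p_floor_and_determinism(rng):
    events = _regular_events(n=60)
    spikes = np.sort(np.concatenate(
        [np.arange(s, e, 0.01) for s, e in events]  # strongly locked
    ))
    p1, obs, ctrl = circular_permutation_test(spikes, events, 500, seed=3)
    p2, _, _ = circular_permutation_test(spikes, events, 500, seed=3)
    assert p1 == p2 == pytest.approx(1 / 500)  # floored at 1/n_permutations
    assert obs.shape == ctrl.shape
    # permutation conserves total spike mass
    assert obs.sum() == pytest.approx(ctrl.sum(), rel=1e-9)


def test_circular_permutation_requires_spikes():
    with pytest.raises(ValueError):
        circular_permutation_test(np.array([1000.0]), _regular_events(n=10))


def test_modulation_with_significance_directions(rng):
    events = _regular_events(n=150)
    # excited unit: much higher rate inside events
    sp_exc = []
    sp_inh = []
    for s, e in events:
        sp_exc.extend(rng.uniform(s, e, 4))
        sp_exc.extend(rng.uniform(s - 0.5, s + 0.5, 2))
        # inhibited: fires in the surround but never inside the event
        pre = rng.uniform(s - 0.5, s - 0.05, 5)
        post = rng.uniform(e + 0.05, s + 0.5, 5)
        sp_inh.extend(pre)
        sp_inh.extend(post)
    res_exc = modulation_with_significance(np.sort(sp_exc), events, seed=1)
    assert res_exc.significance == "excited" and res_exc.i_swr > 0
    res_inh = modulation_with_significance(np.sort(sp_inh), events, seed=1)
    assert res_inh.significance == "inhibited" and res_inh.i_swr < 0


def test_modulation_with_significance_null(rng):
    events = _regular_events(n=100)
    spikes = np.sort(rng.uniform(0, 450, 2000))
    res = modulation_with_significance(spikes, events, seed=2)
    assert res.significance in ("n.s.", "excited", "inhibited")
    assert 0 < res.p_value <= 1.0


def test_classify_group_exhaustive():
    assert classify_group("excited", "excited") == "IAP-and-MAP-SWR+"
    assert classify_group("excited", "n.s.") == "IAP-SWR+"
    assert classify_group("excited", "inhibited") == "IAP-SWR+"
    assert classify_group("n.s.", "excited") == "MAP-SWR+"
    assert classify_group("inhibited", "excited") == "MAP-SWR+"
    assert classify_group("inhibited", "n.s.") == "IAP/MAP-SWR-"
    assert classify_group("n.s.", "inhibited") == "IAP/MAP-SWR-"
    assert classify_group("inhibited", "inhibited") == "IAP/MAP-SWR-"
    assert classify_group("n.s.", "n.s.") == "unclassified"
    with pytest.raises(ValueError):
        classify_group("maybe", "n.s.")


def test_combos_cover_all_significant_outcomes():
    assert sum(COMBOS_PER_GROUP.values()) == 8


def test_expected_group_counts_anchor():
    exp = expected_group_counts(70)
    assert exp == {"IAP-SWR+": 18, "MAP-SWR+": 18,
                   "IAP/MAP-SWR-": 26, "IAP-and-MAP-SWR+": 9}


def test_group_binomial_matches_direct_sum():
    # lower tail
    p = group_binomial_test(3, 70, 1)
    ref = sum(stats.binom.pmf(k, 70, 1 / 8) for k in range(4))
    assert p == pytest.approx(ref)
    assert p < 0.05
    # upper tail
    p_hi = group_binomial_test(30, 70, 2)
    ref_hi = sum(stats.binom.pmf(k, 70, 2 / 8) for k in range(30, 71))
    assert p_hi == pytest.approx(ref_hi)
    with pytest.raises(ValueError):
        group_binomial_test(80, 70, 1)


def test_duration_matched_control(rng):
    short = [SwrEvent(float(k), float(k) + float(d), 5.0)
             for k, d in enumerate(rng.uniform(0.05, 0.12, 60))]
    long_ = [SwrEvent(100.0 + k, 100.0 + k + float(d), 5.0)
             for k, d in enumerate(rng.uniform(0.05, 0.3, 80))]
    gap = abs(np.mean([e.duration_s for e in short])
              - np.mean([e.duration_s for e in long_]))
    ra, rb = duration_matched_control(short, long_, seed=0)
    assert len(ra) == len(rb) > 0
    da = np.array([e.duration_s for e in ra])
    db = np.array([e.duration_s for e in rb])
    # matching shrinks the mean-duration gap between the groups
    assert abs(da.mean() - db.mean()) < gap / 2
    with pytest.raises(ValueError):
        duration_matched_control([], long_)


def test_label_permutation_control_detects_selectivity(rng):
    ev_a = [SwrEvent(float(10 * k), 10.0 * k + 0.1, 5.0) for k in range(40)]
    ev_b = [SwrEvent(1000.0 + 10 * k, 1000.0 + 10 * k + 0.1, 5.0) for k in range(40)]
    spikes = []
    for e in ev_a:  # fires only during class-a events
        spikes.extend(rng.uniform(e.start_s, e.end_s, 5))
    spikes.extend(rng.uniform(0, 1500, 1500))  # background
    out = label_permutation_control(
        np.sort(spikes), {"a": ev_a, "b": ev_b}, n_permutations=200, seed=0
    )
    assert out["p_value"] < 0.05
    with pytest.raises(ValueError):
        label_permutation_control(np.sort(spikes), {"a": ev_a})


def test_joint_modulation_regression_recovers_plane(rng):
    n = 50
    i_map = rng.normal(0, 1, n)
    i_iap = rng.normal(0, 1, n)
    i_joint = 0.3 + 0.6 * i_map + 0.4 * i_iap + rng.normal(0, 0.05, n)
    out = joint_modulation_regression(i_joint, i_map, i_iap)
    np.testing.assert_allclose(out["coef"], [0.3, 0.6, 0.4], atol=0.05)
    assert out["r_squared"] > 0.95
    with pytest.raises(ValueError):
        joint_modulation_regression([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
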