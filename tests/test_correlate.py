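"""Correlograms, PETHs and coincidence measures, against brute force."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swrpipe.correlate import (
    auto_correlogram,
    coincidence_index,
    cross_correlogram,
    nearby_spike_proportion,
    pattern_similarity_index,
    well_entry_peth,
    zero_lag_z,
)


def brute_force_correlogram(a, b, bin_s, window_s, remove_zero_lag=False):
    """O(n*m) reference: nearest-center binning with ties to even."""
    n_half = int(round((window_s / 2.0) / bin_s))
    counts = np.zeros(2 * n_half + 1)
    for ta in a:
        for tb in b:
            d = tb - ta
            if remove_zero_lag and d == 0.0:
                continue
            k = int(np.rint(d / bin_s))
            if abs(k) <= n_half:
                counts[k + n_half] += 1
    total = counts.sum()
    values = counts / total if total > 0 else counts
    return counts, values


def _random_trains(rng, max_n=200, span=20.0):
    a = np.unique(rng.uniform(0, span, rng.integers(1, max_n)))
    b = np.unique(rng.uniform(0, span, rng.integers(1, max_n)))
    return a, b


def test_cross_correlogram_equals_brute_force(rng):
    for _ in range(25):
        a, b = _random_trains(rng)
        cg = cross_correlogram(a, b, bin_s=0.05, window_s=2.0)
        counts, values = brute_force_correlogram(a, b, 0.05, 2.0)
        assert cg.n_events == int(counts.sum())
        np.testing.assert_allclose(cg.values, values, atol=1e-12)


def test_auto_correlogram_equals_brute_force(rng):
    for _ in range(10):
        a, _ = _random_trains(rng)
        cg = auto_correlogram(a, bin_s=0.05, window_s=2.0)
        counts, values = brute_force_correlogram(a, a, 0.05, 2.0, remove_zero_lag=True)
        assert cg.n_events == int(counts.sum())
        np.testing.assert_allclose(cg.values, values, atol=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0, 30, allow_nan=False), min_size=1, max_size=40),
    st.lists(st.floats(0, 30, allow_nan=False), min_size=1, max_size=40),
)
def test_correlogram_symmetry_property(ta, tb):
    a, b = np.unique(ta), np.unique(tb)
    ab = cross_correlogram(a, b, bin_s=0.1, window_s=2.0)
    ba = cross_correlogram(b, a, bin_s=0.1, window_s=2.0)
    # swapping trains negates all lags exactly (nearest-center binning)
    np.testing.assert_allclose(ab.values, ba.values[::-1], atol=1e-12)
    assert ab.n_events == ba.n_events


def test_correlogram_normalization_and_eligibility(rng):
    a = np.sort(rng.uniform(0, 100, 500))
    b = np.sort(rng.uniform(0, 100, 500))
    cg = cross_correlogram(a, b, bin_s=0.01, window_s=1.0, min_coincidences=100)
    assert cg.values.sum() == pytest.approx(1.0)
    assert cg.eligible == (cg.n_events > 100)
    sparse = cross_correlogram(np.array([1.0]), np.array([1.5]), 0.01, 1.0)
    assert not sparse.eligible


def test_correlogram_peak_lag():
    a = np.arange(1.0, 50.0, 1.0)
    b = a + 0.12  # constant 120 ms lag
    cg = cross_correlogram(a, b, bin_s=0.01, window_s=1.0)
    assert cg.peak_lag_s == pytest.approx(0.12)


def test_correlogram_rejects_empty():
    with pytest.raises(ValueError):
        cross_correlogram(np.array([]), np.array([1.0]))


def test_auto_correlogram_speed_filter(rng):
    spikes = np.sort(rng.uniform(0, 100, 400))
    speed = np.where(spikes < 50, 10.0, 0.5)  # first half moving
    cg = auto_correlogram(spikes, 0.05, 2.0, speed_at_spikes=speed,
                          speed_range=(4.0, np.inf))
    ref = auto_correlogram(spikes[spikes < 50], 0.05, 2.0)
    np.testing.assert_allclose(cg.values, ref.values)
    with pytest.raises(ValueError):
        auto_correlogram(spikes, speed_range=(4.0, np.inf))


def test_nearby_spike_proportion_extremes():
    a = np.arange(0.0, 10.0, 0.5)
    assert nearby_spike_proportion(a, a + 0.01) == pytest.approx(1.0)
    far_b = a + 1.13  # within far window, outside near window, off the 0.5 s grid
    assert nearby_spike_proportion(a, far_b) == pytest.approx(0.0)
    assert np.isnan(nearby_spike_proportion(np.array([0.0]), np.array([100.0])))


def test_nearby_spike_proportion_directional_average():
    a = np.array([0.0, 10.0])
    b = np.array([0.01, 10.01, 12.0, 13.0])
    # a->b: both a-spikes have a near partner -> 1.0
    # b->a: all 4 b-spikes are far-coincident, 2 have near partners -> 0.5
    v = nearby_spike_proportion(a, b, near_s=0.05, far_s=3.3)
    assert v == pytest.approx((1.0 + 0.5) / 2)


def test_well_entry_peth_rate_and_normalization(rng):
    entries = np.arange(10.0, 500.0, 10.0)
    spikes = np.sort(rng.uniform(0, 510, 5000))  # ~9.8 Hz homogeneous
    peth = well_entry_peth(spikes, entries, window_s=5.0, bin_s=0.1)
    assert peth.active
    assert peth.normalized_rate.max() == pytest.approx(1.0)
    # flat firing: mean rate close to the true rate everywhere
    assert peth.rate_hz.mean() == pytest.approx(5000 / 510, rel=0.1)
    with pytest.raises(ValueError):
        well_entry_peth(spikes, np.array([]))


def test_well_entry_peth_locates_response():
    entries = np.arange(10.0, 300.0, 10.0)
    spikes = np.sort(np.concatenate([entries + 0.5, entries + 0.52, entries + 0.55]))
    peth = well_entry_peth(spikes, entries, smoothing_sigma_s=0.0)
    assert peth.lags_s[np.argmax(peth.rate_hz)] == pytest.approx(0.5)


def test_pattern_similarity_sign():
    lags = np.arange(-50, 51) * 0.1
    bump = np.exp(-0.5 * ((lags - 1.0) / 0.5) ** 2)  # asymmetric about lag 0
    from swrpipe.correlate import Peth

    def mk(r):
        return Peth(lags, r, r / r.max() if r.max() > 0 else r, r.max() > 0)

    pfc = mk(bump + 0.1)
    iap_like = mk(bump * 2 + 0.1)
    map_like = mk(bump[::-1] + 0.1)
    out = pattern_similarity_index(pfc, [iap_like], [map_like])
    assert out.size == 1 and out[0] > 0
    # constant PFC PETH: no defined similarity
    assert pattern_similarity_index(mk(np.ones_like(lags) * 0 + 0.0),
                                    [iap_like], [map_like]).size == 0


def test_zero_lag_z_detects_coincident_trains(rng):
    base = np.sort(rng.uniform(0, 2000, 4000))
    partner = np.sort(base + rng.normal(0, 0.02, base.size))
    z_coin = zero_lag_z(base, partner)
    shifted = np.sort((partner + 500.0) % 2000.0)
    z_null = zero_lag_z(base, shifted)
    assert z_coin > 3.0
    assert abs(z_null) < 3.0


def test_zero_lag_z_exclusion_and_ineligibility(rng):
    a = np.sort(rng.uniform(0, 100, 200))
    b = np.sort(rng.uniform(0, 100, 200))
    # excluding everything leaves no spikes -> NaN
    assert np.isnan(zero_lag_z(a, b, exclude_intervals=np.array([[0.0, 100.0]])))
    assert np.isnan(zero_lag_z(np.array([1.0]), np.array([2.0])))


def test_coincidence_index_sign(rng):
    base = np.sort(rng.uniform(0, 2000, 3000))
    iap = np.sort(base + rng.normal(0, 0.02, base.size))     # coincident
    mapt = np.sort(rng.uniform(0, 2000, 3000))               # independent
    out = coincidence_index(base, [iap], [mapt])
    assert out.size == 1 and out[0] > 0
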