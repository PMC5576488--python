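"""Band-pass filtering, consensus envelope, noise model and event detection."""

from __future__ import annotations

import numpy as np
import pytest

from swrpipe.behavior import MotionSegmentation
from swrpipe.ripples import (
    ConsensusEnvelope,
    NoiseModel,
    SwrEvent,
    consensus_envelope,
    detect_swrs,
    estimate_noise_threshold,
    ripple_bandpass,
    swr_band_power,
)

FS = 1500.0


def _tone(freq, duration=4.0, fs=FS, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


def test_bandpass_passes_in_band_and_rejects_out_of_band():
    sig = _tone(200.0)
    out = ripple_bandpass(sig[:, None], FS)[:, 0]
    mid = slice(len(sig) // 4, 3 * len(sig) // 4)
    assert np.abs(out[mid]).max() > 0.9  # 200 Hz passes nearly unattenuated
    for f in (50.0, 100.0, 300.0, 500.0):
        rej = ripple_bandpass(_tone(f)[:, None], FS)[:, 0]
        assert np.abs(rej[mid]).max() < 0.05, f


def test_bandpass_zero_phase():
    """A symmetric FIR applied without delay keeps the carrier phase."""
    sig = _tone(200.0)
    out = ripple_bandpass(sig[:, None], FS)[:, 0]
    mid = slice(len(sig) // 4, 3 * len(sig) // 4)
    corr = np.corrcoef(sig[mid], out[mid])[0, 1]
    assert corr > 0.999


def test_bandpass_rejects_low_sample_rate():
    with pytest.raises(ValueError):
        ripple_bandpass(np.zeros((100, 1)), 400.0)


def test_bandpass_requires_rate_for_arrays():
    with pytest.raises(ValueError):
        ripple_bandpass(np.zeros((100, 1)))


def test_consensus_envelope_normalized_to_immobility():
    rng = np.random.default_rng(3)
    filt = rng.normal(0, 1, (30_000, 4))
    imm = np.zeros(30_000, dtype=bool)
    imm[:20_000] = True
    env = consensus_envelope(filt, FS, imm)
    assert env.value[imm].mean() == pytest.approx(0.0, abs=1e-9)
    assert env.value[imm].std() == pytest.approx(1.0, abs=1e-9)
    assert env.n_channels == 4


def test_consensus_envelope_needs_three_channels():
    with pytest.raises(ValueError):
        consensus_envelope(np.zeros((1000, 2)), FS, np.ones(1000, dtype=bool))


def test_consensus_envelope_tracks_burst_amplitude():
    """The envelope during a strong in-band burst far exceeds baseline."""
    rng = np.random.default_rng(4)
    filt = rng.normal(0, 1, (15_000, 3))
    burst = _tone(200.0, duration=0.1) * 10.0
    filt[7000 : 7000 + burst.size] += burst[:, None]
    imm = np.ones(15_000, dtype=bool)
    env = consensus_envelope(filt, FS, imm)
    assert env.value[7000 : 7000 + burst.size].max() > 5 * env.value[:6000].max()


def test_noise_threshold_gaussian_closed_form(rng):
    values = rng.normal(2.0, 3.0, 200_000)
    nm = estimate_noise_threshold(values)
    oracle = nm.mode_value + 3.719 * 3.0
    assert nm.threshold == pytest.approx(oracle, rel=0.05)
    # quantile helper agrees with the stored threshold
    assert nm.mirrored_quantile(0.9999) == pytest.approx(nm.threshold)


def test_noise_threshold_contamination_robust(rng):
    clean = rng.normal(0.0, 1.0, 200_000)
    nm_clean = estimate_noise_threshold(clean)
    contaminated = clean.copy()
    k = clean.size // 100
    contaminated[:k] = rng.normal(9.0, 1.0, k)  # 1% strong outliers
    nm_cont = estimate_noise_threshold(contaminated)
    assert nm_cont.threshold == pytest.approx(nm_clean.threshold, rel=0.10)


def test_noise_threshold_input_validation(rng):
    with pytest.raises(ValueError):
        estimate_noise_threshold(rng.normal(0, 1, 100))
    with pytest.raises(ValueError):
        estimate_noise_threshold(np.zeros(20_000))


def _env(values, fs=1000.0):
    return ConsensusEnvelope(
        np.arange(values.size) / fs, values, 0.0, 1.0, 3, fs
    )


def _noise(threshold=3.0):
    return NoiseModel(mode_value=0.0, threshold=threshold,
                      mirrored_samples=np.zeros(1))


def _all_immobile(duration):
    return MotionSegmentation([("immobility", 0.0, duration)])


def test_detect_requires_min_duration():
    v = np.full(5000, -0.1)
    v[1000:1010] = 5.0  # 10 ms at fs=1000: below the 20 ms minimum
    events = detect_swrs(_env(v), _noise(), _all_immobile(5.0), min_event_s=0.020)
    assert events == []
    v[1000:1025] = 5.0  # 25 ms: accepted
    events = detect_swrs(_env(v), _noise(), _all_immobile(5.0), min_event_s=0.020)
    assert len(events) == 1


def test_detect_extends_to_mean_crossing():
    v = np.full(5000, -0.1)
    v[990:1060] = 1.0       # supra-mean shoulder
    v[1000:1050] = 5.0      # supra-threshold core
    events = detect_swrs(_env(v), _noise(), _all_immobile(5.0))
    assert len(events) == 1
    ev = events[0]
    # extended to the below-mean samples bracketing the shoulder
    assert ev.start_s == pytest.approx(0.989, abs=1.5e-3)
    assert ev.end_s == pytest.approx(1.060, abs=1.5e-3)
    assert ev.peak_env == pytest.approx(5.0)


def test_detect_merges_overlapping_extensions():
    v = np.full(5000, -0.1)
    v[1000:1030] = 5.0
    v[1030:1040] = 1.0      # stays above the mean between the two cores
    v[1040:1070] = 5.0
    events = detect_swrs(_env(v), _noise(), _all_immobile(5.0))
    assert len(events) == 1


def test_detect_discards_movement_starts_and_truncates():
    seg = MotionSegmentation([("immobility", 0.0, 2.5), ("movement", 2.5, 5.0)])
    v = np.full(5000, -0.1)
    v[3000:3050] = 5.0      # starts during movement: dropped
    v[2400:2600] = 5.0      # starts during immobility, crosses into movement
    events = detect_swrs(_env(v), _noise(), seg)
    assert len(events) == 1
    ev = events[0]
    assert ev.start_s < 2.5
    assert ev.end_s == pytest.approx(2.5)  # truncated at the movement boundary


def test_detect_empty_when_below_threshold():
    v = np.full(5000, -0.1)
    assert detect_swrs(_env(v), _noise(), _all_immobile(5.0)) == []


def test_swr_event_duration():
    ev = SwrEvent(1.0, 1.08, 4.2)
    assert ev.duration_s == pytest.approx(0.08)
    assert ev.interval() == (1.0, 1.08)


def test_band_power_marks_edge_events_nan():
    from swrpipe.model import LfpBundle

    rng = np.random.default_rng(8)
    n = int(10 * FS)
    samples = rng.normal(0, 1, (n, 3))
    burst = _tone(200.0, duration=0.1) * 20.0
    samples[3000 : 3000 + burst.size] += burst[:, None]
    lfp = LfpBundle(FS, ["a", "b", "c"], samples)
    ev_in = SwrEvent(3000 / FS, 3000 / FS + 0.1, 5.0)
    ev_edge = SwrEvent(9.95, 9.99, 5.0)
    out = swr_band_power(lfp, [ev_in, ev_edge])
    assert np.isfinite(out[0]) and out[0] > 1.0  # strong burst: high z power
    assert np.isnan(out[1])
    assert ev_in.band_power_z == pytest.approx(out[0])
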