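"""Sharp-wave-ripple detection from multi-tetrode LFP.

The detector works on a *consensus envelope*: each channel is band-passed
to 150-250 Hz, the analytic-signal magnitude is smoothed with a Gaussian
kernel (sigma = 4 ms), and the pointwise median across channels (at least
three) is taken and z-normalized to immobility periods.  The detection
threshold is not a fixed multiple of the SD: the noise distribution is
estimated empirically by locating the mode of the immobility envelope
histogram and mirroring the mass below the mode around it, and the
threshold is the 99.99th percentile of that symmetric noise distribution.
Supra-threshold runs lasting at least 20 ms become events, extended out to
where the envelope returns to the immobility mean; events starting during
movement are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len as fft_next_fast_len
from scipy.ndimage import gaussian_filter1d

from .behavior import MotionSegmentation
from .model import LfpBundle

__all__ = [
    "ConsensusEnvelope",
    "NoiseModel",
    "SwrEvent",
    "ripple_bandpass",
    "consensus_envelope",
    "estimate_noise_threshold",
    "detect_swrs",
    "swr_band_power",
]


@dataclass
class ConsensusEnvelope:
    """Normalized consensus ripple-band envelope at the LFP sample rate."""

    time_s: np.ndarray
    value: np.ndarray
    norm_mean: float
    norm_sd: float
    n_channels: int
    sample_rate_hz: float


@dataclass
class NoiseModel:
    """Empirical mode-mirrored noise distribution of the envelope."""

    mode_value: float
    threshold: float
    mirrored_samples: np.ndarray = field(repr=False)

    def mirrored_quantile(self, q: float) -> float:
        return float(np.quantile(self.mirrored_samples, q))


@dataclass
class SwrEvent:
    """One detected sharp-wave ripple."""

    start_s: float
    end_s: float
    peak_env: float
    band_power_z: float = float("nan")
    content_class: str = "unassigned"
    participants: list[str] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def interval(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)


def ripple_bandpass(
    lfp: LfpBundle | np.ndarray,
    sample_rate_hz: float | None = None,
    band: tuple[float, float] = (150.0, 250.0),
) -> np.ndarray:
    """Zero-phase FIR band-pass of the LFP to the ripple band.

    A linear-phase FIR (Hamming window, transition width 25 Hz, > 40 dB
    stopband) is applied by convolution and the group delay removed, which
    for a symmetric filter gives exact zero phase.
    """
    if isinstance(lfp, LfpBundle):
        samples = lfp.samples
        fs = lfp.sample_rate_hz
    else:
        samples = np.atleast_2d(np.asarray(lfp, dtype=float))
        if samples.shape[0] == 1 and samples.ndim == 2 and np.asarray(lfp).ndim == 1:
            samples = samples.T
        if sample_rate_hz is None:
            raise ValueError("sample_rate_hz required for array input")
        fs = sample_rate_hz
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError(
            f"sample rate {fs} Hz too low for a {lo}-{hi} Hz band (need > {2 * hi})"
        )
    transition = 25.0
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1  # odd -> integer group delay
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")
    out = np.empty_like(samples, dtype=float)
    for ch in range(samples.shape[1]):
        out[:, ch] = signal.oaconvolve(samples[:, ch], taps, mode="same")
    return out


def consensus_envelope(
    filtered: np.ndarray,
    sample_rate_hz: float,
    immobility_mask: np.ndarray,
    smoothing_sigma_s: float = 0.004,
    min_channels: int = 3,
    t0_s: float = 0.0,
) -> ConsensusEnvelope:
    """Median-across-channels smoothed Hilbert envelope, z-scored to immobility.

    Parameters
    ----------
    filtered : ndarray, time x channel
        Ripple-band LFP from :func:`ripple_bandpass`.
    immobility_mask : boolean ndarray, per LFP sample
        Samples during immobility (speed < 4 cm/s); the envelope is
        normalized so these samples have mean 0 and SD 1.
    """
    filtered = np.atleast_2d(filtered)
    n_channels = filtered.shape[1]
    if n_channels < min_channels:
        raise ValueError(f"need at least {min_channels} channels, got {n_channels}")
    n = filtered.shape[0]
    nfft = int(fft_next_fast_len(n))
    env = np.empty_like(filtered, dtype=float)
    for ch in range(n_channels):
        analytic = signal.hilbert(filtered[:, ch], N=nfft)[:n]
        env[:, ch] = gaussian_filter1d(
            np.abs(analytic), smoothing_sigma_s * sample_rate_hz, mode="nearest"
        )
    consensus = np.median(env, axis=1)
    imm = consensus[np.asarray(immobility_mask, dtype=bool)]
    if imm.size == 0:
        raise ValueError("no immobility samples to normalize against")
    mu, sd = float(imm.mean()), float(imm.std())
    if sd == 0:
        raise ValueError("degenerate envelope: zero variance during immobility")
    value = (consensus - mu) / sd
    time_s = t0_s + np.arange(n) / sample_rate_hz
    return ConsensusEnvelope(time_s, value, mu, sd, n_channels, sample_rate_hz)


def estimate_noise_threshold(
    envelope_values: np.ndarray,
    immobility_mask: np.ndarray | None = None,
    percentile: float = 99.99,
    n_bins: int = 200,
    min_samples: int = 10_000,
) -> NoiseModel:
    """Estimate the detection threshold from the mode-mirrored noise distribution.

    The immobility envelope histogram's mode is located (200 equal-width
    bins up to the 99.9th percentile); samples below the mode are mirrored
    around it to form a symmetric noise distribution whose ``percentile``
    quantile is the threshold.  High-amplitude signal above the mode never
    enters the noise model, so the threshold is robust to contamination by
    genuine ripples.
    """
    values = np.asarray(envelope_values, dtype=float)
    if immobility_mask is not None:
        values = values[np.asarray(immobility_mask, dtype=bool)]
    if values.size < min_samples:
        raise ValueError(
            f"need at least {min_samples} immobility samples, got {values.size}"
        )
    if values.std() == 0:
        raise ValueError("degenerate envelope distribution: zero variance")
    upper = np.quantile(values, 0.999)
    lo = values.min()
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, upper))
    k = int(np.argmax(counts))
    mode = 0.5 * (edges[k] + edges[k + 1])
    below = values[values <= mode]
    mirrored = np.concatenate([below, 2 * mode - below])
    threshold = float(np.quantile(mirrored, percentile / 100.0))
    return NoiseModel(mode_value=float(mode), threshold=threshold, mirrored_samples=mirrored)


def detect_swrs(
    envelope: ConsensusEnvelope,
    noise: NoiseModel,
    segmentation: MotionSegmentation,
    min_event_s: float = 0.020,
) -> list[SwrEvent]:
    """Detect SWRs from the consensus envelope.

    Runs above the noise threshold lasting at least ``min_event_s`` are
    extended backward and forward to the nearest crossing of the
    normalized-envelope immobility mean (0); overlapping extended events
    are merged.  Events whose start falls during movement are discarded,
    and an event extending across a movement boundary is truncated there.
    """
    v = envelope.value
    fs = envelope.sample_rate_hz
    t = envelope.time_s
    n = v.size
    min_run = max(1, int(round(min_event_s * fs)))

    above = v > noise.threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[splits + 1]])
    run_ends = np.concatenate([idx[splits], [idx[-1]]]) + 1  # exclusive
    keep = (run_ends - run_starts) >= min_run
    run_starts, run_ends = run_starts[keep], run_ends[keep]
    if run_starts.size == 0:
        return []

    # nearest sample at/below the mean before and after each run
    below_mean = v <= 0.0
    below_idx = np.flatnonzero(below_mean)
    # last below-mean sample strictly before i
    prev_pos = np.searchsorted(below_idx, run_starts, side="left") - 1
    ext_starts = np.where(prev_pos >= 0, below_idx[np.maximum(prev_pos, 0)], 0)
    next_pos = np.searchsorted(below_idx, run_ends - 1, side="right")
    ext_ends = np.where(
        next_pos < below_idx.size, below_idx[np.minimum(next_pos, below_idx.size - 1)], n - 1
    )

    # merge overlapping extended events
    merged: list[list[int]] = []
    for s, e in zip(ext_starts, ext_ends):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])

    immobile = segmentation.intervals_of("immobility")
    events: list[SwrEvent] = []
    for s_idx, e_idx in merged:
        start, end = float(t[s_idx]), float(t[e_idx])
        # start must fall in an immobility interval; truncate at its end
        row = np.flatnonzero((immobile[:, 0] <= start) & (start < immobile[:, 1]))
        if row.size == 0:
            continue
        end = min(end, float(immobile[row[0], 1]))
        if end <= start:
            continue
        peak = float(v[s_idx : e_idx + 1].max())
        events.append(SwrEvent(start_s=start, end_s=end, peak_env=peak))
    return events


def swr_band_power(
    lfp: LfpBundle,
    events: list[SwrEvent],
    band: tuple[float, float] = (150.0, 250.0),
    window_s: float = 0.1,
    step_s: float = 0.01,
) -> np.ndarray:
    """Mean z-scored ripple-band spectral power in the first 100 ms of each event.

    A sliding-window spectrogram (100 ms windows, 10 ms steps, averaged
    across channels) is z-normalized per frequency over the whole session;
    each event receives the mean of the 150-250 Hz rows over windows
    centered within its first ``window_s`` seconds.  Events too close to
    the recording end get NaN.  Results are also written back onto the
    events' ``band_power_z``.
    """
    fs = lfp.sample_rate_hz
    nperseg = int(round(window_s * fs))
    step = int(round(step_s * fs))
    f, times, sxx = signal.spectrogram(
        lfp.samples, fs=fs, axis=0, nperseg=nperseg, noverlap=nperseg - step,
        scaling="density", mode="psd",
    )
    # sxx: freq x channel x time -> average power across channels
    power = sxx.mean(axis=1)
    mu = power.mean(axis=1, keepdims=True)
    sd = power.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (power - mu) / sd
    band_rows = (f >= band[0]) & (f <= band[1])
    times = times + lfp.t0_s
    t_end = lfp.t0_s + lfp.n_samples / fs

    out = np.full(len(events), np.nan)
    for i, ev in enumerate(events):
        if ev.start_s + window_s > t_end:
            continue  # power undefined at the recording edge
        in_win = (times >= ev.start_s) & (times <= ev.start_s + window_s)
        if not in_win.any():
            continue
        out[i] = float(z[np.ix_(band_rows, in_win)].mean())
        ev.band_power_z = out[i]
    return out
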