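# Methods

This document defines every model, parameter, and numerical choice in the
pipeline, the scope of the synthetic generator, and known limitations.
All defaults quoted here live in `swrpipe/config.py` (analysis) and
`swrpipe/synth.py` (generator) and can be overridden via YAML.

## 1. Behavioral segmentation (`swrpipe.behavior`)

- Speed is the magnitude of the finite-difference position derivative,
  Gaussian-smoothed with σ = 0.25 s.
- The session is tiled exactly into alternating **movement**
  (speed > 4 cm/s) and **immobility** segments; `state_at` maps arbitrary
  times back onto this tiling. A stricter 1 cm/s cut is available for
  analyses that require full stillness.
- Occupancy maps use 2 cm bins whose edges are snapped to multiples of the
  bin size; a coordinate that is constant (degenerate range) still gets one
  full bin so that occupancy mass is conserved.
- Reward wells are 10 cm-radius disks; well occupancy intervals are the
  intersection of immobility with presence in a disk, with beam-break
  events taking precedence when provided.

## 2. SWR detection (`swrpipe.ripples`)

Model: ripples are transient 150–250 Hz oscillations visible on several
channels at once, riding on noise whose distribution must be estimated
without assuming the data are event-free.

1. **Band-pass**: zero-phase FIR (Hamming window, numtaps =
   ceil(3.3·fs/25) forced odd, applied via `oaconvolve` with symmetric
   group-delay compensation), band 150–250 Hz.
2. **Envelope**: per-channel Hilbert magnitude (FFT length from
   `scipy.fft.next_fast_len`), Gaussian-smoothed with σ = 4 ms, then the
   **median across channels with at least 3 channels required** — single-channel
   artifacts cannot cross a median of 3+.
3. **Normalization**: envelope z-scored using immobility samples only, so
   the threshold is expressed in immobility-noise units.
4. **Noise model**: the empirical immobility envelope is histogrammed
   (200 bins spanning [min, 99.9th percentile]); the distribution below the
   mode is mirrored around the mode to synthesize an event-free noise
   distribution, and the detection threshold is its **99.99th percentile**.
   On Gaussian noise this converges to mode + 3.719·SD (the closed form
   tested in the suite); under 1% high-amplitude contamination it moves by
   under 10% because the contamination lives entirely above the mode.
5. **Events**: threshold crossings ≥ 20 ms are extended outward to the
   nearest mean (z = 0) crossings, overlapping events are merged, and only
   events **starting during immobility** are kept, truncated at movement
   boundaries.
6. A spectrogram-based 150–250 Hz band power (0.1 s window, 0.01 s step,
   z-scored) is attached per event; events too close to the recording edge
   get NaN rather than a padded estimate.

## 3. Unit classification and spatial coding (`swrpipe.place`)

- **Cell class**: interneuron iff spike width < 0.4 ms **or** mean rate
  ≥ 10 Hz; otherwise pyramidal.
- **Place class** (pyramidal units with > 200 spikes; fewer are
  `excluded`): a unit is **IAP** if its mean rate during immobility at any
  reward well — computed over well-immobility time minus SWR time, with
  SWR spikes removed — reaches 3 Hz; otherwise **MAP**. Removing ripple
  spikes is essential: it distinguishes tonic immobility firing from
  ripple participation.
- **Rate maps**: occupancy-normalized smoothed-counts / smoothed-occupancy
  with a 2 cm-σ Gaussian truncated to a 12 cm extent; never-occupied bins
  are NaN, not zero.
- **Well specificity**: rates at the four wells, normalized to their max,
  weight unit vectors 90° apart; the index is resultant length over total
  weight. Endpoints: 1 for a single active well, 0 for equal rates,
  √2/2 for an equal adjacent pair.
- Supporting statistics: median speed at spike times, and place coverage
  (fraction of occupied bins ≥ 20% of peak, occupied meaning ≥ 0.1 s).

## 4. Temporal correlation (`swrpipe.correlate`)

- **Cross-correlograms** use 10 ms bins with nearest-bin-center assignment
  (`np.rint(lag/bin)`, ties-to-even) so that `xcorr(a,b)` is exactly the
  reverse of `xcorr(b,a)`; pairs are enumerated with `searchsorted` windows
  rather than dense outer differences. Pairs need > 100 coincidences in the
  window to be eligible, and normalized correlograms divide by the total
  in-window count.
- **Nearby-spike proportion**: for each spike of one train, whether the
  other train fires within ±50 ms, referenced to whether it fires within
  ±3.3 s, averaged over both directions.
- **Well-entry PETHs**: ±5 s, 0.1 s bins, σ = 0.1 s smoothing, expressed
  as rates.
- **Similarity index**: Pearson correlation of a PFC unit's correlogram
  with the IAP template minus its correlation with the MAP template.
- **Coincidence index**: difference of zero-lag z-scores (0.1 s bins over a
  ±20 s window).

## 5. SWR content statistics (`swrpipe.content`)

- An event's **participants** are units with ≥ 1 spike in `[start, end)`
  (half-open, so a spike exactly at the end boundary belongs to the next
  event if any).
- Events are labeled MAP-only / IAP-only / joint / unassigned from
  participant classes.
- **Independence expectation** for joint events:
  `(n_map_only + n_joint)·(n_iap_only + n_joint) / n_total`, compared with
  a 1-degree-of-freedom chi-square goodness-of-fit on the joint/non-joint
  split.
- **Pairwise coactivity**: each pair's observed coincident-participation
  count is z-scored against a null built by independently permuting each
  unit's participation vector across events (`rng.permuted`, 5000
  permutations). Pair seeds derive from an FNV-1a hash of the sorted unit
  ids XOR the global seed (mod 2³¹−1), so results are order-invariant and
  reproducible.
- Joint-event latencies between class onsets are reported only for joint
  events, truncated at event boundaries.

## 6. PFC modulation (`swrpipe.pfc`)

- **Modulation index** `I_SWR = (r_SWR − r_baseline)/r_baseline`, where
  `r_SWR` is the rate over the mean event duration from event start and
  `r_baseline` is the rate over the surrounding 1 s. For gain-2 events of
  0.1 s in a 1 s window the closed form is 9/11 ≈ 0.818, which the
  acceptance suite checks.
- **Significance**: circular permutation test. Each permutation rotates
  the spike train by a random offset (wrapping), the PETH (±0.5 s, 10 ms
  bins, vectorized `bincount`) is recomputed, and the statistic is the
  squared deviation of the PETH from its mean over the mean-duration span.
  p-values are floored at 1/n_permutations (1000 by default) — a
  permutation test cannot certify p = 0.
- Units need ≥ 10 events and ≥ 1 Hz to be tested. Significance and sign
  for IAP-events and MAP-events separately map to four groups:
  **IAP-SWR+**, **MAP-SWR+**, **IAP/MAP-SWR-** (suppressed for either),
  and **IAP-and-MAP-SWR+**. Of the 8 possible
  significant sign combinations, 2/2/3/1 fall in each group, so the
  chance expectation for a group is `round_half_away(c·n_significant/8)`
  and each observed count gets a one-sided exact binomial test at
  p = c/8.
- Controls: duration-matched surrogate events, label-permutation nulls,
  and a joint regression of modulation on both class rates.

## 7. Synthetic session generator (`swrpipe.synth`)

Scope: the generator produces sessions that are *sufficient to validate
the pipeline*, not biophysically realistic recordings.

- **Behavior**: alternating movement/immobility bouts, durations
  N(6.6, 1) s clipped to [3, 12] s, shuttling between four corner wells
  80 cm apart; trapezoidal speed profiles with 0.3 s ramps and a 0.2 s
  stationary pad so segmentation boundaries are unambiguous.
- **CA1 units** (defaults 30 MAP / 10 IAP / 2 interneurons): MAPs are
  inhomogeneous Poisson with Gaussian place fields (20 Hz peak, σ = 8 cm),
  speed-gated and theta-modulated, realized by thinning; IAPs fire at 8 Hz
  during immobility at their home well; interneurons are high-rate and
  narrow-spiked.
- **LFP**: four channels of 1/f (pink) noise at 1500 Hz. SWRs are injected
  at 0.4 Hz during immobility as raised-cosine-windowed 200 Hz bursts with
  amplitude 5× the in-band noise SD.
- **Event content**: each injected event draws a class with probabilities
  (0.67, 0.26, 0.07) for MAP-only/IAP-only/joint, then participants with
  probability 0.15 each (at least one forced), and injects their spikes
  inside the event. Non-injected pyramidal background spikes are removed
  within ±50 ms of every event (`swr_silence_margin_s`) so the recorded
  participant lists are exactly the truth labels — without this, tonic
  IAP/MAP background firing inside events would contradict the truth by
  construction.
- **PFC units** (default 20: 6 IAP-locked, 6 MAP-locked, 5 inhibited,
  3 flat) modulate their rate around events of the matching class with
  gains 4 / 4 / 0.15 / 1.
- All randomness flows from one `numpy` `default_rng` seed; generation is
  bit-reproducible.

## 8. Numerical and I/O choices

- Ties-to-even nearest-center correlogram binning (exact symmetry, matches
  the brute-force oracle bit-for-bit).
- Mode-mirroring for the noise model instead of fitting a Gaussian
  (robust to contaminated upper tails).
- `well_specificity` snaps results below 1e-12 to exactly 0 and clips to
  ≤ 1: with equal rates the resultant is analytically zero but
  `cos(π/2)` round-off leaves ~7e-17, and normalized weights can overshoot
  1 by one ulp. The snap threshold (1e-12) is far below any
  scientifically meaningful specificity.
- Permutation p-values are floored at 1/n_permutations.
- CSV round-trips use `float_precision="round_trip"` so written sessions
  re-read bit-identically; HDF5 files are written with
  `track_times=False` so byte content is deterministic.
- All intervals are half-open `[start, end)`; spike membership, interval
  intersection, and subtraction are implemented once in `swrpipe.model`
  and property-tested against pointwise membership.

## 9. Limitations

- The generator's LFP is additive pink noise + stereotyped bursts; it does
  not model sharp-wave polarity, layer-dependent phase, movement artifacts,
  or electrode drift, so detector performance numbers quoted by the tests
  bound performance on this model only.
- Spike sorting is assumed perfect: units arrive pre-sorted with known
  widths. Contamination and lost spikes would degrade the
  classification-rate thresholds in ways the suite does not measure.
- The peri-event background silencing (Section 7) is a coherence device of
  the generator, not a claim about biology; real sessions have background
  firing inside ripples, and content labels there carry that ambiguity.
- The circular permutation test assumes approximate stationarity of the
  background rate over the session; strong slow drift inflates its type-I
  error.
- The four-group PFC chance model assumes the 8 significant sign
  combinations are equiprobable under the null; correlated IAP/MAP event
  populations violate this mildly.
- Expected counts and percentages in `verify-anchors` are arithmetic
  identities of the statistics as implemented, verified exactly; no other
  empirical claims are made beyond quantities the test suite computes.
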