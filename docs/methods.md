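# Methods

This note records the models, conventions and numerical choices behind
mepkit, including the places where the underlying procedure is commonly
described loosely and a concrete convention had to be fixed.

## Data model and conventions

- Sweeps are stored in canonical `[samples × channels × sweeps]` order;
  readers accept any stored axis order via a layout descriptor and
  transpose on load. 2-axis input is treated as single-channel.
- Sample indexing is 0-based. Epoch windows are half-open
  `[start_ms, stop_ms)` relative to sweep onset, where onset is the end of
  stimulation (acquisition frames start at the stimulus trigger). An epoch
  therefore has `floor((stop − start)/1000 · fs)` samples — 70 samples for
  the typical 8–22 ms window at 5 kHz.
- Trials per intensity may be ragged; storage stays a flat sweep axis with
  cumulative-sum offsets. Trial removal drops whole sweeps (all channels):
  per-channel removal is not supported because annotation is per sweep.
- Records and masters are JSON manifests referencing session containers by
  relative path — diffable text instead of an opaque binary container. The
  first session of a record is the baseline by construction; a master
  refuses records with unequal session counts.

## Preprocessing

- The optional band-pass is a Butterworth with default edges 5 and 600 Hz,
  applied forward and backward (zero phase; effective attenuation doubles).
  The order is selected automatically for 4 dB passband ripple and 30 dB
  stopband attenuation. The order-selection procedure needs stopband edges
  that the published defaults do not specify; they are set at `0.5·low_hz`
  and `min(1.25·high_hz, 0.98·Nyquist)`.
- The mains notch is a second-order IIR notch at 60·k Hz, k ≤ 6, quality
  factor 30 (configurable), applied zero-phase.
- Filtering, when enabled, is applied to whole sweeps *before* epoch
  extraction so forward-backward edge transients stay outside the analysis
  window. Filtering is off by default.
- There is no automated artifact rejection. `suggest_outliers` is advisory:
  it flags trials whose deviation from their intensity block's median
  exceeds `z` times a robust scale. The scale is a session-pooled MAD
  (×1.4826) rather than a per-block MAD: with the usual ~5 trials per
  intensity a per-block MAD is degenerate and flags good trials, while
  trial scatter is close to homoscedastic across intensities.

## Quantification

- AUC is the trapezoidal integral of the rectified epoch, in signal·seconds.
- RMS uses the same trapezoidal discretization
  (`sqrt(trapz(f²)/(T2−T1))`), which makes the Jensen relationship
  `RMS ≥ AUC/duration` hold exactly, with equality for constant |f|.
- Peak-to-peak uses the raw (unrectified) epoch and is offset-invariant.
- Latency is the time from epoch start (end of stimulation) to the first
  sample where the rectified trace reaches
  `base + pct/100·(max|f| − base)`. The baseline `base` is the mean
  rectified amplitude over a leading window (default 2 ms; a zero-length
  window gives base = 0). The rectified trace is scanned so negative-going
  onsets are detected. Epochs that never cross are NaN; per-intensity means
  exclude them and report the excluded count. Recruitment curves are never
  fit to latency values (they do not follow a sigmoid), enforced at the
  fitting boundary and in the CLI.
- Per-intensity values are plain arithmetic means over surviving trials —
  no trimming or winsorizing.

## Recruitment-curve fitting

Model: `y(x) = P + (M−P)/(1 + Q·exp(−e^L·(x−K)))`. The logarithmic slope
`L` enters through `e^L`, guaranteeing a positive growth rate. `Q` is fixed
at the lowest-intensity mean response (floored at 1e−6; `q=1` override
available for the standard logistic) and is not optimized, leaving four
free parameters.

**Identifiability.** With `Q` fixed from data, `K` is not the half-maximum
point: the curve's midpoint is `K + ln(Q)/e^L` (`SigmoidParams.midpoint`),
and `(K, Q)` trade off exactly (`Q·e^{−r(x−K)}` depends only on
`ln Q + rK`). The midpoint is the identifiable location parameter; use it
when comparing fits, and expect raw `K` values to differ between fits with
different fixed `Q`.

**Initial estimates.** On the sorted responses, `P0`/`M0` are medians of
5-value windows centered on the nearest-rank (`ceil(p·n)`) 5th/95th
percentile positions, clipped at the vector ends (an even clipped window
takes the mean of its two central values). The empirical half-maximum
location is the mean of the two intensities whose responses are closest to
`(P0+M0)/2`; `K0` is placed so the initial curve's midpoint lands there
given the fixed `Q`. `L0` comes from the steepest discrete slope via the
logistic identity (max derivative = `rate·(M−P)/4`). Flat data
(`M0 ≤ P0`) take a degenerate path (`P0 = M0 = mean(y)`) and still run the
optimizer, which the stall rule terminates.

**Fit error.** `RMSE of residuals / (max(y) − min(y))` — scale-free, so the
default tolerance of 0.1 means the same thing in µV and mV. Flat data use a
unit denominator.

**Stopping rules.** One *iteration* is one optimizer round: a Nelder–Mead
run to internal convergence (`xatol` 1e−8, `fatol` 1e−10, ≤ 800 inner
iterations), restarted from the best point so far. After each round, in
order of precedence: (1) error < tolerance (default 0.1) → stop;
(2) the round improved the error, but by less than 0.01 → stop
(diminishing returns); (3) no strict improvement for 10 consecutive rounds
→ stop (stall; the counter resets on any improvement ≥ 0.01). Choosing the
round granularity (rather than inner Nelder–Mead steps) is deliberate: per
inner step the tolerance rule would accept the first parameter vector whose
error dips under 10% of the data range, which is far too coarse to recover
parameters; per round, a clean dataset converges in one round and noisy
data stop at the best locally attainable fit. A fit that ends by
stalling with error above tolerance is retried once, deterministically,
from perturbed initials (K and L × 1.1), and the better result is kept.

**Diagnostics.** R² = 1 − SSres/SStot (constant data: 1 if residuals are
zero, NaN otherwise). Saturation: least-squares line through the last three
points after normalizing y by the maximum mean response and x by the median
intensity step; the curve is saturated iff the slope is strictly below 0.2.
A non-saturated curve raises a warning — never an error — and analysis
proceeds.

## Curve comparison

- **MEP metric** (vertical cut): the target response is `m_pct%` of the
  *baseline's upper asymptote*; the baseline curve is inverted to find
  `Stim_M`, every curve is evaluated there, and values are reported as
  percent of the baseline value (baseline ≡ 100). `--as-change` reports
  value − 100 instead.
- **Stimulation metric** (horizontal cut): the reference intensity is
  `s_pct%` of the *baseline session's* maximum intensity (not a
  per-condition maximum); the baseline response there is the level every
  curve must attain. Curves whose asymptote falls short yield NaN plus a
  warning instead of an error, so group summaries degrade gracefully.
- **Slope metric**: a smooth sigmoid has no region of constant nonzero
  derivative, so the "linear portion" is operationalized as the contiguous
  dense-grid region where the derivative is ≥ 90% of its maximum
  (configurable fraction); the reported slope is the regression slope over
  that region, optionally divided by the baseline slope.
- Group summaries are per-condition means with standard errors
  (sample SD, n−1 denominator, over √n) across records; NaN markers are
  excluded with counts reported, and a single contributing record gives
  SE = NaN. `direct_mep_comparison` pools all trial values per condition
  (grand mean ± SE) for designs where no curve is fit.

## Synthetic data

Each simulated sweep is a Morlet-like waveform — a 300 Hz carrier under a
Gaussian envelope (SD 1.5 ms) at 10 ms onset plus N(0, 0.5 ms) latency
jitter — whose peak-to-peak amplitude equals the ground-truth sigmoid at
that trial's intensity plus zero-mean Gaussian trial-to-trial variability
(default SD 0.05 mV, i.e. 5% of the 1 mV half-maximum response; floored at
zero amplitude). The scale factor is computed on the sweep's actual sample
grid, so with noise and jitter disabled the quantified peak-to-peak
reproduces the sigmoid exactly — a closed-form oracle for the whole
quantify→fit chain. Defaults mirror a typical rodent preparation: 5 kHz
sampling, intensities from 0.5 mA in 0.5 mA steps, 10 trials per intensity,
sigmoid 0.1–2.0 mV with midpoint 2.5 mA. Optional nuisances: 60 Hz line
noise, slow baseline drift, and injected artifact trials (sweep × scale
plus a square transient) for screening scenarios.

What the generator does *not* emulate: broadband background EMG, waveform
shape changes with intensity, electrode drift across sessions, or any
biophysical motor-unit recruitment — the amplitude–intensity law is
imposed, not emergent. Green end-to-end tests therefore establish that the
pipeline recovers an imposed sigmoid under amplitude noise and jitter, not
that it is robust to every artifact of real recordings.

Randomness: all draws come from per-sweep substreams seeded by
(seed, sweep index), so one trial's data never depends on how many trials
are generated; the same seed reproduces sessions bit-identically.

## Known limitations

- Only the generalized-logistic family is fitted; no alternative curve
  shapes and no confidence intervals on parameters.
- No inferential statistics across conditions — the bar data (means ± SE)
  are intended as input to the user's own statistics.
- Proprietary acquisition formats (CED/TDT/ADInstruments) are not parsed;
  sessions must first be exported to MAT or HDF5 containers.
- Multi-channel trial removal drops whole sweeps; channel-specific artifact
  handling would require per-channel annotation.
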