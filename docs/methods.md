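# Methods

## Problem and pipeline overview

The package quantifies how the temporal relationship between a
*C. elegans* AFD thermosensory neuron and its postsynaptic AIY
interneuron changes with feeding state, from paired calcium-imaging
traces recorded under time-varying thermal stimuli, plus the behavioral
counterpart from multi-worm-tracker trajectories on a thermal gradient.

The analysis chain is:

1. **Preprocessing** (`preprocess`). Raw fluorescence F(t) is rescaled
   as dF/F0 = (F - F0)/F0 with F0 the per-animal minimum (taken exactly,
   not a percentile), mapped affinely onto [0, 1], and high-pass
   filtered (zero-phase Butterworth, order 4, cutoff 0.01 Hz) to remove
   bleaching and baseline drift. We do not re-normalize after
   detrending. Constant traces are rejected rather than silently
   zeroed: they would poison both normalization and phase estimation.
2. **Cross-correlation** (`xcorr`). The non-stationary correlogram
   C(t, tau) = y_AFD(t) y_AIY(t + tau) is a raw product of the [0, 1]
   signals, with no mean subtraction or variance scaling, so its time
   axis shows *when* the neurons co-activate. Cells whose t + tau falls
   outside the record are undefined, never zero-padded (padding
   fabricates anti-correlation at edges). Statistics are taken per
   animal: the mean of the interior local maxima of C(t, tau*) inside a
   time or temperature window, one scalar per animal. C(t, tau*) is not
   smoothed before the maxima scan.
3. **Phase** (`phase`). Each signal is differentiated (central
   differences; second-order accurate, no phase bias), the derivative
   low-passed (zero-phase Butterworth designed for <= 3 dB ripple at the
   0.12-Hz passband edge and >= 20 dB attenuation at the 1.2-Hz
   stopband edge), and the analytic signal z = x + i x_hat formed via
   the FFT Hilbert transform. The instantaneous phase shift is
   phi(t) = theta_AFD - theta_AIY wrapped to [-pi, pi]; phi = 0 is
   in-phase, +/-pi anti-phase, phi > 0 means AIY lags AFD. phi is
   sampled at interior local maxima of the AIY derivative and
   summarized per animal by the circular mean weighted by the AIY
   derivative amplitude R_k at each event (floored at 0), so weak,
   noise-dominated events do not distort the summary.
4. **Spectra** (`spectral`). Single-sided DFT amplitude of the
   mean-subtracted signal, scaled so a unit sinusoid at an on-grid
   frequency reads ~1; no taper by default (records hold an integer
   number of stimulus cycles, so leakage is minimal), Hann optional.
   Epoch segmentation centers equal windows on interior stimulus maxima
   and re-times them so the peak sits at t = 0.
5. **Statistics** (`stats`). Brunner-Munzel for linear quantities
   (mid-rank relative effect, t statistic with Satterthwaite degrees of
   freedom, Wald CI on the relative effect); V test (u = V sqrt(2n),
   one-sided normal tail) for circular bias toward a pre-specified
   direction; Watson U^2 against a von Mises with estimated parameters
   (Lockhart-Stephens critical-value table, kappa-interpolated) as the
   guard for the V test's distributional assumption;
   Mardia-Watson-Wheeler uniform-scores test for two-sample circular
   homogeneity (chi-square with 2 df when both n >= 10, seeded
   permutation reference otherwise); Bonferroni division for family
   control.
6. **Behavior** (`behavior`). Moving vectors over a 1-s lag (14 frames
   at 13.5 Hz, round-half-up), direction folded to [0, 180] degrees
   (0 = warmer), curving rate as the unsigned angle per second between
   successive moving vectors. Omega turns: body length (polyline
   through the 11 tracker points) below the animal's own mean minus
   1.5 SD *and* curving rate above 90 deg/s; reversals: 3-frame mean
   curving rate above 150 deg/s; runs of qualifying frames merge into
   events, and the two detectors are independent (a frame may satisfy
   both).

## Sampling-rate assumptions

The imaging frame interval is not fixed by the data format; the package
default is dt = 0.5 s, which resolves the 0.025-Hz stimulus band and
the ~15-s lags of interest. At this rate the Nyquist frequency (1 Hz)
lies below the 1.2-Hz derivative-filter stopband edge; the filter
design clips the stopband specification just below Nyquist, because
frequencies above Nyquist do not exist in the sampled record and the
attenuation requirement is vacuous there. At finer sampling the full
specification is honored (verified by test at dt = 0.1 s).

## Edge handling in the phase pipeline

The FFT Hilbert transform assumes periodic extension, so the first and
last 1/passband-edge seconds (~8.3 s) of the analytic signal are
flagged unreliable and excluded from event sampling. When the full
cohort pipeline runs on detrended records, the exclusion widens to
max(1/passband-edge, 1/detrend-cutoff) = 100 s per end: the zero-phase
high-pass leaves transients of roughly one filter time constant on
ramp-bearing records, and their large derivatives would otherwise enter
the amplitude-weighted mean with the highest weights.

## Synthetic-data generator

`synth` emulates the study conditions so every stage is testable
without downloads.

**Stimuli.** Osci1721 (17.5-21.0 C) and Osci1523 (15.8-23.0 C,
lower bound selectable since both 15.0 and 15.8 are reported) are
linear ramps spanning the bounds over 600 s with a 0.5-C-amplitude
0.025-Hz sinusoid superimposed (the ramp protocols' oscillation
frequency is not printed; we reuse the 0.025 Hz of the trend-free
protocol). Osci17 is 15 pure cycles at 0.025 Hz around 16.75 C
(amplitude 0.25 C, 600 s, no trend). Fluc1719 is Gaussian white noise
low-passed at 0.1 Hz (so the stimulus is physically smooth), scaled and
clipped to 17.5-19.5 C, fully seeded.

**AFD.** Threshold-rectified temperature tracking: activity
proportional to max(0, T - T*), min-max normalized, default threshold
T* = 17.0 C for 20-C-cultivated animals (below every ramp minimum so
the response spans the record; tests use 16.0 C for Osci17). This is a
static nonlinearity, not a dynamical thermoreceptor model; it suffices
for phase-relation and spectral tests.

**AIY.** Convolution of AFD activity with the two-Gaussian synaptic
kernel K(t) = U+ exp(-t^2/2 s+^2) + U- exp(-(t - tau)^2/2 s-^2),
truncated at +/- (4 max(s+, s-) + |tau|), rectified at zero, min-max
normalized. Condition defaults:

| condition | U+ | U- | s+ (s) | s- (s) | tau (s) | effect |
|---|---|---|---|---|---|---|
| well_fed | 1.0 | 0 | 2 | - | 0 | AIY tracks AFD, phi ~ 0 |
| starved | 1.0 | -2.5 | 10 | 3 | 0 | oscillation inverted, phi ~ +/-pi |

The starved kernel produces anti-phase coupling through the kernel's
frequency response, not through an explicit delay: the slow excitatory
Gaussian passes the ramp/baseline (keeping the pre-rectification signal
positive over most of the record) while attenuating the 0.025-Hz band
~1000-fold, and the sharp inhibitory Gaussian passes that band with a
negative sign. For a periodic stimulus this is observationally
identical to a half-period response delay. Note that the superficially
natural alternative — equal-magnitude inhibition *delayed* by half a
period — does **not** produce anti-phase output: suppressing the
troughs re-excites the peaks (sin(wt - pi) = -sin(wt)), doubling the
in-phase component; a test documents this behavior.

**Cohorts.** Per-animal jitter on the threshold (SD 0.1 C) and kernel
magnitudes (5% SD), white measurement noise of SD 0.05 on the
normalized activity (a typical indicator-noise floor relative to a
full-scale transient), and export as fluorescence-like counts
F = 100 (1 + activity) so the dF/F0 chain applies end to end. A
ground-truth table (per-animal threshold, kernel, seed) accompanies
every cohort. Because one kernel governs a whole recording, the
phase relation is stationary by construction, so cohort-recovery checks
pool events over the full (edge-trimmed) record; temperature-windowed
pooling is implemented and tested as a feature, but for these
synthetic phase-locked cohorts the AIY-derivative peaks always occur at
the same stimulus phase — and hence the same temperature leg — so a
narrow low-temperature window can be structurally empty in a way real,
noisier data are not. This is the main respect in which passing tests
do not certify behavior on real recordings; the others are the absence
of motion artifacts, indicator nonlinearities, and non-stationary
(temperature-dependent) synaptic state within a recording.

**Tracks.** Discrete-time 13.5-Hz locomotion at 120 um/s with white
heading noise (20 deg/s) and a restoring turn bias (10 deg/s x sin of
the heading) toward the warm +x axis, on a 9-cm plate with reflecting
walls. Omega turns are injected as 3-s episodes of 130 deg/s turning
with the body length scaled by 0.6; reversals as instantaneous 180-deg
heading flips. Injection times are Poisson (default 0.01 /s each, >= 5 s
apart) and returned as ground truth; wall reflections that turn the
heading by more than 150 deg genuinely reverse the trajectory and are
recorded in the reversal ground truth as well. Bodies are straight
11-point polylines behind the centroid — adequate because the omega
detector uses only relative length drops, not posture.

## Numerical choices

- Local maxima are interior points strictly greater than both nearest
  distinct neighbors; a plateau counts once at its first index;
  plateaus touching a record end are discarded.
- Circular means with zero total weight, or a resultant below 1e-12 of
  the total weight (e.g. two equal antipodal events), return NaN
  ("undefined direction") rather than an arbitrary angle.
- Brunner-Munzel under complete separation (zero rank variance in both
  groups) returns the relative effect 0 or 1 with an infinite statistic
  and p = 0 instead of dividing by zero.
- The Mardia-Watson-Wheeler permutation fallback (either n < 10) uses
  9999 permutations by default and flags samples with more than 20% of
  pooled values tied.
- Uniform-grid validation tolerates 1% step jitter; larger jitter is a
  format error naming the offending animal.

## Problem sizes in the test suite

Simulation-based checks use 600-s records at dt = 0.5 s (1200 samples),
cohorts of 16 animals per condition over 20 seeds, 500 null
replications per test for type-I calibration, 100 replications for
power/level checks, and 20 tracks of 600 s for detector scoring; these
sizes give the Monte-Carlo margins the assertions need while keeping
the default suite fast.

## Known limitations

- The Hilbert phase is meaningful only for band-limited, oscillatory
  signals; the derivative + 0.12-Hz low-pass stage enforces this but
  non-oscillatory episodes yield low-amplitude events that the
  R-weighting, not an explicit mask, down-weights.
- Watson's U^2 critical values are tabulated at alpha in
  {0.10, 0.05, 0.01} only; other levels are rejected rather than
  interpolated across alpha.
- Whether the per-event weight should be the raw AIY derivative, its
  absolute value, or the analytic-signal envelope is ambiguous; the raw
  derivative floored at zero is used, which ignores events where AIY is
  falling.
- The behavioral model has no speed modulation, head-swing dynamics, or
  isothermal tracking; it exists to exercise the detectors and plate
  summaries, not to reproduce thermotaxis strategy.
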