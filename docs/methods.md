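# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices made where the design was open.

## Synthetic sessions

A session consists of three sample-0-aligned streams: marker trajectories
at 100 Hz, and a 32-channel biosignal block (24-channel EEG cap including
VEOG and both mastoids, plus 8 bipolar sEMG channels) on one 500 Hz
clock. Durations default to 30 s blocks; the three treadmill speed labels
(1.4 / 2.0 / 2.6 km/h) map to stride cadences of 0.55 / 0.70 / 0.85 Hz and
to beta-power scales of 1.2 / 1.0 / 0.8, reflecting the higher
sensorimotor beta power of slow walking. All randomness flows from a
single integer seed; a fixed seed reproduces a session bit for bit.

### Marker templates

The right-heel height over one cycle is a fixed sum of four harmonics
whose coefficients were chosen, by numerical search, so that

* the trace has exactly one prominent minimum per cycle (the cycle
  boundary used by the detector),
* the left-right heel-height difference (the left leg is the right leg
  delayed half a cycle) crosses zero exactly twice per cycle, and
* the left-heel maximum falls strictly between that crossing and the
  second heel-toe crossing.

Within this family the geometry is rigid: the gap between the template's
maximum and minimum cannot be made smaller than about 0.17 cycle, which
pins the end of mid-stance (the left-heel maximum rule) near 70 % of the
cycle. The six event fractions realized are 0.120, 0.360, ~0.588
(template-determined), ~0.702 (template-determined), 0.760 and 0.860,
giving phase durations MSW 12 %, TSW 24 %, LR 23 %, MST 11 %, TST 6 %,
PSW 10 %, ISW 14 %. These differ from physiological norms (real mid-stance
is longer, terminal stance much longer); the generator's purpose is exact
event geometry, not biomechanical fidelity. The heel-toe difference and
the anteroposterior heel separation are one- and three-harmonic designs
whose crossings/extrema sit at the free fractions above; the third
harmonic in the separation trace (coefficient 0.2 < 1/3) sharpens its
extrema without adding new ones, which keeps event detection stable under
marker noise. Event times are located on the analytic templates by
Brent root finding and bounded minimization at import time, to ~1e-10
cycle precision; ground truth stores them in seconds per cycle.

### Biosignals

Each sEMG channel is `carrier_amp * envelope * carrier + baseline noise +
50 Hz line`, the carrier being unit-variance Gaussian noise band-limited
to 30 Hz - 0.9×Nyquist (the acquisition rate of 500 Hz cannot carry the
450 Hz band edge; the full 30-450 Hz band-pass applies after resampling
to 1 kHz). The envelope is a per-phase gain table (textbook-like defaults:
TA active in swing and loading, GM at push-off, VM at loading/mid-stance,
BF at terminal swing), Gaussian-smoothed with a 50 ms kernel, multiplied
by `1 + 0.5 * texture` where the texture is unit-variance noise smoothed
to a ~0.12 s correlation time. The texture matters: without within-phase
envelope structure, band-power curves are featureless over a single phase
and no estimator could distinguish coupling strengths (see below).

Each scalp EEG channel is pink noise plus a beta oscillation (carrier
frequency uniform in 17-24 Hz) under a smooth stochastic amplitude
envelope of the same texture family. A coupling entry
`(channel, muscle, phase, κ)` replaces that envelope inside the named
phase by `(1-κ) * own + κ * muscle envelope` (moment-matched over the
phase samples), so κ = 1 copies the muscle's envelope exactly and κ = 0
leaves the channels independent. VEOG carries 200 ms raised-cosine blink
transients at Poisson times (0.2 /s) with peak amplitude 20 a.u. —
several times the background EEG, as real blinks are — bleeding into
Fp1/Fp2/FPz with fixed weights (0.5/0.5/0.6). Amplitudes are arbitrary
units; defaults are `noise_sd` 1.0, beta amplitude 1.5×speed scale, EMG
carrier 2.0, line amplitude 0.5.

What the generator does **not** emulate: volume conduction between scalp
channels, electrode drift, movement artifacts, muscle cross-talk,
non-stationary cadence, or any true neuromuscular delay. Passing tests
therefore demonstrate that the pipeline recovers what it is designed to
recover under controlled conditions, not that it would perform at these
levels on human recordings.

## Preprocessing

Order of operations: mastoid re-reference ((M1+M2)/2 subtracted from EEG
only) → zero-phase 2nd-order Butterworth high-pass 0.5 Hz and low-pass
50 Hz on EEG/EOG → polyphase resampling to 1 kHz → FastICA over the EEG
channels with removal of components whose |Pearson r| against VEOG
exceeds 0.7 → elliptic 30-450 Hz band-pass (order 4, 0.5 dB ripple, 40 dB
stop) plus 501-tap least-squares FIR 48-52 Hz notch on EMG, both applied
forward-backward → db4 wavelet shrinkage on EMG (level
`floor(log2(rate/90))`, i.e. 3 at 1 kHz; universal threshold with the
MAD/0.6745 noise scale from the finest details; soft thresholding).
Markers are linearly interpolated onto the 1 kHz clock. Channel labels
and order never change; a PrepReport logs every filter and removal.

FastICA is not guaranteed to reach tolerance on this mixture (each
channel carries its own pink noise and beta source plus the shared blink
train — an over-complete problem). The blink component is nonetheless
isolated reliably; the report records the iteration count and a
`raise_on_nonconvergence` flag upgrades non-convergence to an error for
strict use.

A robust-z rule (channel RMS > 5 MAD above the median) stands in for
visual artifact inspection; flagged channels are zeroed, never dropped,
so shapes are stable. A manual list is also accepted.

## Event detection

Cycles: prominent minima (prominence ≥ 25 % of range, spacing ≥ half the
autocorrelation-estimated period) of the smoothed right-heel height; an
autocorrelation peak below 0.3 raises a periodicity error. Events: zero
crossings by sign change plus linear interpolation, extrema by discrete
argmax on the admissible sub-interval, all on 5-sample moving-average
smoothed traces (symmetric smoothing leaves noise-free crossings and
extrema in place). Sub-sample event times are kept in seconds; public
indices round half-up. The mid-stance rule has two published readings;
`mst_rule="left"` (maximum of the left heel, the default) or `"right"`
(maximum of the right heel). The default generator geometry realizes the
left reading; under the right reading the detector still returns the
admissible-window maximum.

On noise-free synthetic sessions all six events are recovered within one
marker sample (measured ≤ 0.45); with additive noise of 1 % of each
trace's range, ≥ 95 % of cycles have all events within 3 samples
(measured ~99.7 % over 20 seeds).

## Features and classification

SSC uses the strict product convention at threshold 0 (count of strict
local extrema), making it amplitude-scale invariant; a nonnegative
threshold gates reversals by amplitude. MPF uses a Hann-windowed
full-segment periodogram excluding DC. One instance per (cycle, phase);
runs shorter than 8 samples are skipped with a warning. On phase-gated
synthetic sessions the discriminative signal is a mixture of phase
duration (SSC is a count, not a rate) and the envelope-dependent spectral
balance between carrier band, baseline noise and line residue.

Classification: features z-scored on training statistics; RBF-SVM
(one-vs-one); PSO (20 particles, 50 iterations, inertia 0.72,
c1 = c2 = 1.49, bounds log10 C ∈ [−2, 3], log10 γ ∈ [−4, 1]) minimizes
1 − 5-fold CV accuracy on the training split; the best (C, γ) is refit on
the full training split and evaluated on the held-out third. Per-phase
accuracy is the per-class recall (confusion diagonal over row sum); the
reported SD is across the seven per-phase accuracies.

The Mann-Whitney comparison of accuracy samples uses an exact two-sided
null by full enumeration of group assignments (valid under ties) for
groups of ≤ 8 values, and the tie-corrected normal approximation
otherwise.

## TFCMI

Channels are z-scored per analysis window before the Morlet transform
(ω₀ = 6, L2-normalized kernels, 1 Hz frequency steps; 10 rows for
16-25 Hz EEG, 16 rows for 30-45 Hz sEMG). Histogram entropies use 40
equal-width bins on each curve's own [min, max]; joint histograms bin
each axis independently the same way; TFMI is floored at zero and
normalized by `sqrt(H_i H_j)` (alternatives `min` and `joint` give the
same unit diagonal and are selectable). The diagonal is set to exactly 1.

Two per-phase estimators are provided. `epoch_mode="cycle"` extracts each
cycle's phase segment, Fourier-resamples it to a fixed 2000-sample epoch,
computes one matrix per cycle and averages. `epoch_mode="concat"`
computes band-power curves once over the whole session, pools the
phase's samples across cycles and computes a single matrix. The cycle
estimator mirrors a fixed-epoch analysis convention but has a structural
limitation for inference: over a 100-350 ms phase window the band-power
curves are smooth (the 20 Hz wavelet's time resolution is ~50 ms), the
40-bin joint histogram concentrates near a curve, and the MI estimate
saturates regardless of the true coupling — measured coupling sensitivity
is ~0.01 against seed noise of the same size. The pooled estimator sees
hundreds of envelope degrees of freedom and recovers the injected
coupling strength cleanly (mean normalized TFCMI rising ~0.11 → 0.15
across κ = 0 … 1, strictly increasing on 10-seed means). Quantitative
coupling comparisons should therefore use `"concat"`; the per-phase maps
and topographies are available under either mode.

Two estimator biases worth knowing: (i) plug-in histogram MI is biased
upward by finite samples (~0.36 bits for independent N = 2000 pairs at
40×40 bins), so normalized baselines sit near 0.1-0.2, not 0; (ii) the
baseline depends on the pooled sample size and hence on phase duration —
shorter phases have higher baselines. Between-phase comparisons of raw
TFCMI therefore confound duration with coupling; the package's own
coupling checks compare each phase against its κ = 0 counterpart
(generated with the same seed; the generators are RNG-aligned so the
difference isolates the coupling effect).

## Statistics

Lobe means group the 13 movement-related electrodes as frontal
{F3, F4, F7, F8, Fz}, central {C3, C4, Cz}, parietal {P3, P4, P7, P8, Pz}
(standard 10-20 regional grouping; configurable). One-way ANOVA is the
classical F test with an explicit zero-within-variance flag; post-hoc
comparisons default to Tukey HSD with a Bonferroni-Welch alternative.
ANOVA replicates are per-cycle lobe means (cycle-mode estimates), pooled
across sessions when several are analyzed.

## Problem sizes

Default analyses use single 30 s sessions (~19-21 cycles at 0.70 Hz
cadence). The package's own verification uses 10-seed sweeps for coupling
recovery, 20-seed sweeps for noisy event recovery, and 3 pooled sessions
for the feature-classification checks — sizes at which every reported
property is stable.

## Known limitations

* The cycle-mode TFCMI estimator is reported for completeness but should
  not be used for coupling inference (see above).
* The generator's phase-duration split is template-bound and not
  physiological; absolute per-phase numbers (e.g. SSC counts) reflect it.
* Recognition accuracies on synthetic sessions are not comparable to
  human-subject accuracies; the generator's class structure is both
  easier (stationary, noise-controlled) and harder (no true
  inter-muscle coordination patterns) than real data.
* On-disk sessions use the package's native container only (TSV markers,
  NPZ biosignal block, JSON sidecars); clinical formats such as EDF or
  BrainVision triplets are not parsed — convert externally and build a
  `MultiChannelRecording` directly.
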