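# Methods

This note documents the models, numerical choices and known limitations of
`retinacuity`. It covers what the synthetic data emulate (and what they do
not), the exact signal-processing and decoding procedures, and the design
decisions taken where more than one reasonable choice existed.

## Experimental model being emulated

The pipeline targets recordings of retinal ganglion cells (RGCs) in
photoreceptor-degenerated retina interfaced to a high-density CMOS
microelectrode array: a 65 × 65 grid of recording sites at 16 µm pitch
interleaved with a 32 × 32 grid of capacitive stimulation electrodes at
32 µm pitch (≈1 × 1 mm). Stimuli are grating pattern reversals: two
complementary striped patterns ("phase 1" / "phase 2") shown in alternation.

* **Electrical modality** — each repetition presents four cycles of a 40 Hz
  sinusoidal carrier (2.5 V peak-to-peak, 15 µC/cm²) on the phase-1
  electrodes during 0–100 ms and on the phase-2 electrodes during
  350–450 ms, followed by a 250 ms inter-stimulus gap (700 ms period).
  Electrical widths are restricted to multiples of the 32 µm electrode
  pitch.
* **Optogenetic modality** — the projected grating reverses every half
  cycle of the reversal frequency: 200 ms per phase at 2.5 Hz, 50 ms at
  10 Hz, with no gap.

## Synthetic data generator

**Selectivity.** Each unit carries a ground-truth RFR drawn from a
three-component mixture: probability 0.4 of being unselective (RFR = 0) and
0.3 each of RFR = ±r. This reproduces the qualitative bimodality of
measured selectivity-index distributions without asserting unpublished
parameters; r is the knob every experiment turns. Expected per-phase rates
invert the RFR definition at a base rate B (default 8 Hz):
FR₁ = B(1 + RFR), FR₂ = B(1 − RFR), so the empirical RFR of long
simulations converges to the ground truth. The base rate is a configurable
default, not an assertion about rd10 spontaneous activity, which is not
characterised here.

**Spiking.** Counts per phase window are Poisson with mean rate × duration;
within-window times are uniform, except in the electrical modality where
each spike is assigned a random carrier cycle and jittered (σ = 1.5 ms)
around the cycle midpoint, reproducing carrier-locked rasters. There is no
refractory period, adaptation, fading, or cross-unit correlation — so
passing tests demonstrate the pipeline's statistical behaviour, not
robustness to the temporal structure of real spike trains.

**Raw traces** (optional) are strictly additive: Gaussian sensor noise,
biphasic spike templates (~0.7 ms, negative-leading, Gaussian-lobed, spread
over channels within 40 µm of the soma with a 20 µm spatial constant), and
a modality-specific artifact. Electrical: a 40 Hz sinusoid inside active
phase windows whose amplitude decays with the channel's distance to the
nearest active electrode (50 µm constant, 1% crosstalk of the half
peak-to-peak drive). Optogenetic: a sawtooth drift (default 5 mV per
400 ms) reset by a 200 µs alternating-sign transient; a reset also occurs
at t = 0, so a 2 s trace holds 5 resets. Axon paths are straight polylines
toward an array edge and never emit spikes, making selectivity somatic by
construction. The default sampling rate is 20 kHz — enough to resolve both
the 200 µs reset (4 samples) and the 5 kHz filter corner; it is
configurable.

**QC metadata** (IsoIBG, separability, SNR) would normally come from spike
sorting, which is out of scope; the generator assigns them (SNR = template
amplitude / noise SD; the others drawn from configurable ranges, with a
configurable fraction of IsoIBG set to missing) so that curation is
testable.

## Signal processing

Chains: optogenetic = 2nd-order high-pass Bessel at 200 Hz then 2nd-order
low-pass Bessel at 5 kHz; electrical = 4th-order high-pass Butterworth at
1 kHz then 2nd-order low-pass Bessel at 3 kHz. Analog prototypes are
realised as digital second-order sections via the bilinear transform
(Bessel designs use magnitude normalisation so the nominal cutoff is the
−3 dB point). All filters are applied forward–backward (`sosfiltfilt`):
spike timing relative to the phase windows must not shift, and that
phase-free property is preferred over matching hardware latency even though
zero-phase application doubles the effective order (the nominal orders
above are kept as designed, not halved).

Sensor-reset removal operates per channel: (1) the trace is segmented at
the reset times; (2) each inter-reset segment has its drift curve — a
2nd-order Savitzky–Golay smoothing with an 800 µs window, rounded to the
nearest odd sample count (17 at 20 kHz) — subtracted; segments shorter than
the window skip this step with a logged warning; (3) samples inside each
200 µs reset window are blanked *before* the 100 Hz 2nd-order Butterworth
high-pass, so the transient cannot ring into its neighbourhood; (4) the
blanked samples are replaced by noise drawn with replacement (seeded) from
the lowest-variance 50 ms stretch of the same processed channel. On a pure
sawtooth the residual is at rounding level (the quadratic smoother fits a
ramp exactly), and a spike 5 ms after a reset keeps its amplitude relative
to a reset-free control; note the drift subtraction itself removes ~30% of
the raw template amplitude in both arms, which is why the spike template's
lobes (~0.2 ms) are kept narrow relative to the smoother window.

## Unit analysis

Curation keeps units with numeric IsoIBG, separability ≥ 2.5 and — only
for electrical recordings — SNR in [3.3, 14]; bounds are inclusive and
configurable; an empty survivor set is a warned-about result, not an error.
The firing-rate matrix has one row per (repetition, phase) and one column
per unit: spike count in the phase window divided by the window duration;
inter-stimulus intervals are excluded; silent units keep their all-zero
columns. RFR uses the mean rate per phase across repetitions (a single FR
per phase, matching the index's definition) rather than per-repetition
ratios; when both means are zero the index is undefined and reported as 0
with an `undefined` flag so downstream matrices stay dense.

**Dip test.** Hartigan's dip — the sup-norm distance from the empirical CDF
to the nearest unimodal CDF — is computed with the classical iterative
GCM/LCM scheme over a shrinking modal interval. The implementation is
validated in the test suite against a linear-programming oracle that solves
the defining minimax problem on a fine x-grid (unimodal shape constraints
become slope inequalities; the grid enforces them between data points,
which is what distinguishes separated clusters from unimodal data). The
p-value is a bootstrap tail probability under a uniform null (the dip's
null distribution depends on sample size only and is cached per size);
fewer than 10 defined RFR values yield an explicit not-computable result.

## Decoding

Binary classification of grating phase from population rate vectors:
standard score per feature with mean and population SD estimated on the
training rows only (zero-variance features map to 0), rbf-kernel SVM with
C = 1 and scikit-learn's variance-scaled kernel width (`gamma="scale"`;
the width is not otherwise specified), stratified 10-fold cross-validation
with shuffling at a fixed seed. The primary path is 10-fold CV over the
full dataset; an optional `holdout_fraction=0.2` reproduces a single 80/20
split. Re-fitting the scaler inside each fold avoids train/test leakage —
accepted even if the original workflow scaled once globally. f1 is computed
from pooled fold confusion counts with phase 1 as the positive class; both
algebraic forms (harmonic mean of precision/recall and the TP-form) are
asserted to agree at machine precision on every call. Chance level for
balanced phases is 0.5.

**Feature importance.** An rbf machine has no primal coefficients, so
"most informative units" is operationalised as permutation importance: the
drop in held-out f1 when one unit's column is shuffled, averaged over
shuffles and over the stratified folds. Averaging over folds (rather than
one 80/20 split) is necessary for a usable estimate at these sample sizes;
importances still saturate to zero when the decoder is at ceiling with
redundant units, so they are informative in the below-ceiling regime. The
"contributing fraction" counts units whose importance exceeds 5% of the
maximum (threshold echoed in the output, configurable).

## Acuity curve

`run_pipeline` runs generate → curate → rate matrix → RFR/dip → decode for
each width in the grid (optogenetic default {5, 10, 20, 30, 50, 100,
500} µm with 500 µm as control; electrical default {32, 64, 128} µm),
deriving one child seed per width from the master seed. The selectivity-vs-
width model is configurable: a saturating profile
r(w) = r_max (1 − e^(−w/s)) (defaults r_max = 0.8, s = 15 µm) models the
loss of differential activation below a spatial scale, and a step profile
is used for threshold-recovery experiments. The acuity threshold is the
smallest width from which every larger width sustains mean f1 ≥ the
criterion (default 0.75, the midpoint of chance and perfect; the curve
itself is the primary output since no standard criterion exists).

Bar width converts to spatial frequency as cpd = M/(2w): one grating cycle
spans two bars, and the retinal magnification M = 35 µm/deg is calibrated
so that 10 µm ↔ 1.75 cpd (which also gives 32 µm → 0.546… → printed 0.54;
reported cpd values are truncated, not rounded, to two decimals — the only
rule consistent with both printed pairs).

## Problem sizes and determinism

Default experiment sizes (40 units, 60 repetitions per phase, 50 seed
replicates for chance-level estimates, 20 replicates for threshold
recovery) are chosen to match the scale of a single ex vivo recording
session while keeping full runs fast on one CPU. Every stochastic stage
takes an explicit seed; identical configs produce byte-identical reports.

## Limitations

* Synthetic spike trains are conditionally independent Poisson; real RGC
  responses have refractoriness, latency structure, correlated noise and
  possible fading, none of which are modelled.
* The decoder's reported scores on synthetic data characterise the
  pipeline, not biological acuity; with no deposited raw recordings the
  original ex vivo f1 values are not reproducible here.
* Spike sorting is out of scope: ground-truth unit identities are used
  downstream, and sorting-quality metrics are simulated inputs.
* The dip test's bootstrap uses a uniform null; p-values for strongly
  discretised RFR distributions (heavy ties) are conservative.
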