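# retinacuity

Inferring the spatial resolution of artificial retinal stimulation from the
spiking of retinal ganglion cell (RGC) populations.

Retinal prostheses and optogenetic therapies both aim to restore vision in
photoreceptor-degenerated retina (e.g. the rd10 mouse model of retinitis
pigmentosa) by driving the surviving RGCs directly — electrically through a
high-density CMOS microelectrode array, or optically through
channelrhodopsin. A central question is the *spatial* resolution such
stimulation achieves: how narrow can the bars of an alternating grating
stimulus be before the RGC population stops telling the two grating phases
apart?

`retinacuity` implements that analysis as a tested, reusable pipeline, with a
synthetic-data module standing in for ex vivo recordings so every stage runs
and is testable without any data download:

1. **synthetic recordings** — ground-truth RGC populations with per-unit
   phase selectivity, phase-locked Poisson spike trains (carrier-locked for
   40 Hz electrical stimulation), and optional raw multichannel voltage
   traces with modality-specific artifacts;
2. **signal processing** — the two band-filter chains (2nd-order Bessel
   200 Hz–5 kHz for optogenetic data; 4th-order Butterworth 1 kHz high-pass
   plus 2nd-order Bessel 3 kHz low-pass for electrical data) and removal of
   the periodic 200 µs sensor-reset artifact with Savitzky–Golay drift
   subtraction;
3. **unit analysis** — QC curation (IsoIBG present, separability ≥ 2.5, SNR
   in [3.3, 14] for electrical recordings), per-repetition per-phase
   firing-rate matrices, and the per-cell selectivity index

   RFR = (FR₁ − FR₂) / (FR₁ + FR₂) ∈ [−1, 1],

   whose distribution is tested for unimodality with Hartigan's dip test
   (implemented in-package with a bootstrap p-value);
4. **decoding** — standardisation z = (x − µ)/σ fitted on training folds
   only, an rbf-kernel SVM (C = 1) under stratified 10-fold
   cross-validation, scored with f1 = 2PR/(P+R) ≡ TP/(TP + (FP+FN)/2),
   plus permutation feature importances;
5. **acuity report** — the f1-vs-bar-width curve over a grating width grid,
   an acuity threshold (smallest width sustaining f1 ≥ 0.75), and conversion
   of bar widths to cycles per degree (cpd = M / 2w with retinal
   magnification M = 35 µm/deg, so 10 µm ↔ 1.75 cpd and 32 µm ↔ 0.54 cpd).

## Worked example

```python
import retinacuity as ra

config = ra.PipelineConfig(
    modality=ra.Modality.OPTOGENETIC,
    widths_um=(5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 500.0),
    reversal_frequency_hz=2.5,
    n_units=40,
    n_repetitions=60,
    selectivity=ra.step_selectivity(30.0, r_high=0.8),  # selective only at >= 30 um
    seed=100,
)
result = ra.run_pipeline(config)
for e in result.curve.entries:
    print(f"{e['bar_width_um']:>6.0f} um  f1 = {e['f1_mean']:.3f} +/- {e['f1_sd']:.3f}"
          f"  ({e['cpd']:.2f} cpd)")
print("acuity threshold:", result.curve.threshold_width_um, "um")
```

prints

```
     5 um  f1 = 0.521 +/- 0.162  (3.50 cpd)
    10 um  f1 = 0.494 +/- 0.119  (1.75 cpd)
    20 um  f1 = 0.472 +/- 0.123  (0.87 cpd)
    30 um  f1 = 1.000 +/- 0.000  (0.58 cpd)
    50 um  f1 = 1.000 +/- 0.000  (0.35 cpd)
   100 um  f1 = 1.000 +/- 0.000  (0.17 cpd)
   500 um  f1 = 1.000 +/- 0.000  (0.03 cpd)
acuity threshold: 30.0 um
```

Below the 30 µm step in the simulated selectivity the decoder sits at its
chance level of 0.5 (the two phases are indistinguishable); at and above it
the population decodes the phase perfectly, and the estimated acuity
threshold recovers the width at which selectivity appears. `ra.write_report`
saves the curve (JSON + CSV), f1 bar plots and RFR maps.

The same stages are scriptable from the shell:

```sh
retinacuity simulate --modality optogenetic --bar-width 30 --out bundle/
retinacuity run --modality electrical --n-units 40 --out report/
```

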