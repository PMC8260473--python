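# catrace

Automated calcium-transient analysis for cardiomyocyte fluorescence imaging.

Cyclic calcium transients drive cardiomyocyte contraction and relaxation, and
their kinetics change with pacing rate, disease mutations and drugs.
Experiments on iPSC-derived or isolated adult cardiomyocytes routinely record
hundreds of cells as fluorescence image stacks (Fluo-4, GCaMP/R-GECO, or the
ratiometric dye Fura-2), and the bottleneck is turning those stacks into
per-cell kinetic parameters reproducibly, without manual tracing. `catrace`
is a pipeline for exactly that: image stacks (or pre-extracted traces) in,
per-cell parameter tables, quality-control flags and irregular-beat reports
out.

## What it computes

For each cell the pipeline extracts the summed fluorescence inside a fixed
mask per frame, optionally removes photobleach drift with a second-degree
polynomial fitted to baseline-phase samples, detects transient onsets as
prominent peaks of the difference array `d[i] = F[i+1] − F[i]` (50% minimum
prominence; traces above 100 FPS are decimated for onset detection only),
crops each beat starting 10% of the pacing cycle before its onset, and
averages the beats into a mean transient. From the mean transient it
measures, in the field's standard notation:

- **F₀** — baseline fluorescence, the mean over the final 20% of the cycle,
  and **F_max/F₀**, the normalized peak. To stabilize timing parameters a
  working baseline is redefined as `F₀ + 0.03·(F_max − F₀)`.
- **T₁₀/T₅₀/T₉₀/T_on** and **T₁₀/T₅₀/T₉₀/T_off** — linearly interpolated
  times at 10/50/90/100% of the recalculated magnitude on the rising limb
  (from the interpolated transient foot) and falling limb (from the peak);
  **CD** = T_on + T_off is the transient duration.
- **τ (tau)** — decay constant from a least-squares fit of
  `f(t) = a·e^{b·t} + c` to the decaying arm, `τ = −1/b`, with the fit R²
  reported for quality control.
- **SNR** — mean above-baseline signal divided by the SD of below-baseline
  values; records below 15 are flagged as unreliable.
- Beat-to-beat interval statistics, pacing-adherence, and per-beat
  classification of secondary deflections as EAD-like (during the decay
  limb) or DAD-like (after return to baseline), with contaminated beats
  excluded from parameter averaging.

Ratiometric (Fura-2) recordings are converted to absolute [Ca²⁺] (nM) via
the standard ratiometric equation `[Ca²⁺] = K_d·β·(R − R_min)/(R_max − R)`
or an empirical monotone calibration built from (known-calcium, ratio)
points, then analyzed by the same temporal pipeline.

A fully ground-truthed synthetic generator (`catrace.synthetic`) produces
paced transient waveforms, noise at a target SNR or as a multiple of the
final-300-ms SD, linear/exponential baseline drift, injected EAD/DAD bumps,
multi-cell image stacks with rod-shaped beating cells and rounded static
dead cells, and ratiometric channel pairs — every test in the suite runs
against its dense-grid oracle.

## Worked example

```python
from catrace import (AnalysisConfig, CalciumTransientModel, WaveformSpec,
                     add_noise, make_transient_trace)

# a 1 Hz, 5-beat recording at 100 FPS with noise targeting SNR 20
trace, truth = make_transient_trace(WaveformSpec(pacing_hz=1.0, n_beats=5,
                                                 fps=100.0, tau_off=300.0))
noisy = add_noise(trace, target_snr=20.0, seed=1, truth=truth)

res = CalciumTransientModel(noisy, config=AnalysisConfig(pacing_hz=1.0)).fit()
print(res.summary())
```

```
Calcium Transient Analysis Results
==============================================
Cell id                                0
Beats averaged                         5
Baseline F0                        109.2 AU
Peak Fmax                          203.7 AU
Magnitude                          94.56 AU
Fmax/F0                            1.866 
T10 on                             1.561 ms
T50 on                             7.804 ms
T90 on                             24.45 ms
T on (to peak)                      48.6 ms
T10 off                            38.03 ms
T50 off                            185.9 ms
T90 off                            486.5 ms
T off (full decay)                 662.9 ms
Transient duration CD              711.5 ms
Decay constant tau                 307.1 ms
Fit R^2                           0.9994 
SNR                                19.52 
Beat-to-beat                        1000 ms
----------------------------------------------
Total beats                            5
Irregular beats                        0
Adheres to pacing                   True
Flags                       multi_crossing
```

The recovered decay constant (307.1 ms) matches the generator's dense-grid
oracle (307.3 ms for this waveform) to 0.1%, T₅₀ on/off agree with the
oracle within a frame, F_max/F₀ 1.866 vs 1.871, and the measured SNR hits
the requested 20. The `multi_crossing` flag notes that noise produced more
than one threshold crossing (the first is used) — benign here because five
beats were averaged.

From a shell, the same pipeline runs over directories:

```sh
catrace simulate --n-cells 3 --seed 7 --out demo        # synthetic traces
catrace analyze-traces demo --fps 100 --out demo/results
catrace report demo/results/run_manifest.json
catrace analyze /path/to/tiff_stacks --fps 25 --pacing-hz 0.5
```

Outputs are CSV (and spreadsheet) parameter tables — one row per cell, or
per beat with across-beat SDs in per-beat mode — plus an irregularity report
and a JSON run manifest that accounts for every input file.

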