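# Methods

This note records the models, conventions and numerical choices behind
`catrace`, and what the synthetic benchmarks do and do not demonstrate.

## Trace extraction and masking

The cell mask is computed once from the pixelwise time-average of the stack
and applied unchanged to every frame, so the measured region is the cell
footprint at maximum relaxation. In multi-cell (low magnification) mode the
mean image is band-passed with a difference of Gaussians (σ = 2 px and
20 px, configurable), contrast-equalized (CLAHE, clip limit 0.01, ~8×8
tiles), thresholded by Otsu's method, cleaned by one erosion + one dilation
with a 3-px disk, and labeled. Regions are rejected when they are smaller
than 200 px, rounder than eccentricity 0.75 (rounded cells are almost always
dead), not brighter than background + 2 SD in the raw mean image (guards
against equalization promoting noise texture on sparse fields), or larger
than 3× the median accepted area (touching cells are flagged as possible
merges rather than split — user review, not watershed, resolves them). In
single-cell (high magnification) mode the largest thresholded component is
the footprint and no elongation filter applies. A cell's raw trace is the
sum of pixel intensities in its region per frame; the background estimate
subtracted from it is the per-frame mean of all pixels outside every
detected region (eroded by 3 px against halos), scaled by the cell area.

## Photobleach / baseline-drift correction

Drift from photobleaching or dye loss is modeled by a second-degree
polynomial in time, which captures linear trends exactly and exponential
trends to second order over a recording. The polynomial is fitted to
baseline-phase samples only — the lowest-quartile values within each
pacing-cycle window — so transient peaks do not bias the trend. Cycle
windows are aligned to the trace *end*: every full window then covers the
same beat phase, and a partial pre-stimulus head (whose baseline sits below
the steady-state diastolic level) is dropped instead of faking a trend on
drift-free data. The fitted trend minus its first value is subtracted
(anchoring preserves the absolute intensity scale; constant offsets cancel
in ratio parameters). Policy: `off` passes traces through bit-identically,
`force` always corrects, and `auto` corrects only when the fitted trend
changes by more than 3% of its initial value — the same scale as the
baseline redefinition, so sub-threshold trends are ones the redefinition
already absorbs.

## Transient segmentation and parameters

Onsets are peaks of the first-difference array with prominence at least 50%
of the trace's maximum peak prominence (scale-free per trace) and at least
0.4 cycles apart. Above 100 FPS the trace is integer-decimated to ~100 FPS
for onset detection only — oversampling shrinks point-to-point differences —
and each onset is mapped back and refined to the native-rate difference
maximum; all parameters are computed on native-rate data. Manual onset
frames (e.g. pacing event markers) may be supplied instead.

Each beat is cropped from `onset − 0.10·cycle` to the next onset minus the
same offset (clamped at frame 0 with a flag; a trailing partial beat is
dropped), and beats are averaged pointwise after truncation to the shortest
segment, with the pointwise SD retained.

From the averaged transient: F₀ is the mean of the final 20% of the cycle;
F_max the maximum; magnitude their difference; the working baseline is
redefined as F₀ + 0.03·magnitude and the magnitude recalculated against it.
Timing parameters are first linear-interpolated crossings of 0/10/50/90% of
the recalculated magnitude: the rising (T_on) family is referenced to the
interpolated 0% crossing (the transient foot), the falling (T_off) family
to the peak sample (the rising 100% point is the first sample attaining
F_max — the peak is a sampled extremum and is not interpolated), and
CD = T_on + T_off. First crossings are monotone in threshold level by
construction, which guarantees T₁₀ ≤ T₅₀ ≤ T₉₀ ≤ T on both limbs;
noise-induced extra crossings take the first and raise a `multi_crossing`
flag. The 3% redefinition barely moves the mid-range thresholds (<5% on
noiseless synthetic transients) while making the near-baseline thresholds
(T₉₀_off, T_off) well-defined at all — an exponential tail approaches its
baseline asymptotically, so a 0% redefinition would leave the full-decay
time unstable.

Tau is the least-squares fit of `a·e^{b·t} + c` (b < 0 enforced by bounds)
to the decaying arm from the peak sample to the end of the cycle, with
`τ = −1/b`; initialization uses a = recalculated magnitude,
b = −ln 2 / T₅₀_off, c = redefined baseline. The fit R² is reported; a
record is flagged `poor_tau_fit` when R² < 0.95 **or** when τ exceeds 3×
the fitted window — in that regime an exponential is indistinguishable from
a straight line and τ is unresolved. The exponential-plus-offset form and
τ = −1/b are the standard parameterization for indicator decays and are
implemented as such.

## Signal-to-noise ratio

SNR = mean(values above baseline − baseline) / SD(values below baseline),
with F₀ as the baseline; records below 15 are flagged unreliable. The
definition is implemented literally: the numerator subtracts the baseline
before averaging (the unsubtracted variant is not implemented). One
consequence worth knowing: when a transient has not fully decayed by the
end of the cycle, the below-baseline population contains genuine decaying
signal, so even a noiseless trace has finite SNR (~25 for the default
synthetic waveform). The generator's target-SNR mode therefore saturates —
targets above the clean-trace ceiling produce (near-)zero added noise —
which is the correct inversion of the definition, not a defect.

## Irregular beats (EAD/DAD)

A trace is non-adherent when more onsets are detected than pacing justifies
(tolerance: one extra beat). Within beats, aberrations are found on the
*residual* of each segment against the periodically extended mean transient
of the trace: subtracting the beat shape cancels the decay slope, so a
bump's residual amplitude equals its injected amplitude regardless of
phase. Positive residual peaks qualify as events under a dual criterion —
prominence ≥ 10% of the recalculated magnitude and ≥ 3× the residual noise
SD (robustly estimated as 1.4826·MAD) — excluding a small window around the
upstroke/peak, where sub-frame segmentation jitter produces spikes. Events
before the mean transient has returned to the redefined baseline are
EAD-like; later events, including those landing in the next segment's
pre-upstroke head (attributed to the preceding beat), are DAD-like. When a
first pass finds events, the template is rebuilt from uncontaminated beats
and detection repeated once, restoring full bump amplitude in the residual.
Any beat containing an event is excluded in full from parameter averaging;
the report carries total/irregular/excluded counts, per-event
classifications and beat-to-beat statistics. Detection requires adequate
trace quality and is skipped, with a flag, below the SNR-15 threshold.
Detection weakens for DAD phases within ~0.1 cycle of the next upstroke,
where the bump straddles the segment boundary.

## Ratiometric calibration

Parametric mode uses the standard ratiometric (Grynkiewicz-form) equation
`[Ca²⁺] = K_d·β·(R − R_min)/(R_max − R)`; ratios at or above R_max are
clipped just below it with a flag. Empirical mode interpolates user points
with a monotone piecewise-cubic (PCHIP) map, requiring ≥ 3 strictly
monotone points; conversions outside the calibrated range are flagged. A
centered moving-average companion (window 3 samples, configurable) is
produced alongside the always-retained raw concentration trace, and the
temporal pipeline runs unchanged on concentration traces, reporting
baseline, peak and amplitude in nM.

## Synthetic data and ground truth

The generator's transient is phenomenological: per beat,
`g(t) = (1 − e^{−t/τ_on})·e^{−t/τ_off}` normalized to unit peak, summed
over beats and scaled to `baseline + magnitude·g`. Twenty virtual warm-up
beats precede the recording so it starts at the steady-state diastolic
level, as continuously paced cells do. Defaults describe a typical 1 Hz
recording at 100 FPS: baseline 100 AU, magnitude 100 AU (F_max/F₀ ≈ 2),
τ_on = 15 ms (time to peak ≈ 46 ms), τ_off = 300 ms, first upstroke at
100 ms. The pacing-rate family scales magnitude by `pacing^−0.3`, τ_off by
`pacing^−0.4` and τ_on by `pacing^−0.15`, giving the qualitative
physiological trend of smaller, faster transients at higher rates. Noise is
additive white Gaussian, scaled either to a multiple of the SD of the final
300 ms of the clean trace or, in target-SNR mode, solved by a deterministic
fixed-point against the pipeline's SNR definition (the below-baseline
population is re-selected on the noisy trace, so a closed-form variance
split would overshoot). Drift multiplies the baseline component by a linear
or exponential decay reaching `1 − fraction` at the trace end; the
transient amplitude is left untouched, consistent with a subtractive
correction model. EAD/DAD events are Gaussian bumps (σ = 25 ms) at a
phase validated against the class (EAD during decay, DAD after full decay).
Image stacks render anti-aliased ellipses whose interiors follow their
waveforms, static circles for dead cells, constant background and
shot-like noise.

Ground-truth parameters come from brute-force evaluation of the continuous
waveform on a 1000×-oversampled grid, applying the same *definitions* as
the analysis (segment window, tail-window baseline, redefinition,
interpolated crossings) in an independent implementation — so oracle values
are what a perfect analysis of this waveform would report, not the raw spec
constants. In particular the oracle's `tau_fit` is the best-fit exponential
to the continuous decaying arm: the product waveform's decay is only
asymptotically exponential (the activation term perturbs it near the peak,
by ~2% of τ_off at τ_on = 15 ms), and `tau_fit` — which converges to τ_off
as τ_on → 0 — is the right reference for a decay-arm fit.

What the generator does **not** emulate: biophysical membrane currents and
their conductance-dependent variability (cell-to-cell variation is
parameter jitter instead), motion artifacts, optical blur/PSF, pink or
correlated noise, and partial photobleach of the transient amplitude.
Passing benchmarks therefore demonstrates correctness of the measurement
pipeline on realistic waveform shapes, not robustness to every artifact of
real microscopy.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use desk-scale conditions chosen
to exercise each behavior with comfortable statistics: 5-beat (8-beat for
drift) 1 Hz traces at 100 FPS; 100 seeded traces per SNR level across
targets 15–70; 20 seeded 192×192 fields of 5 rod + 3 round cells at 25 FPS;
200 seeded beats with one injected EAD/DAD each (amplitude 15–30% of
magnitude, SNR 20, EAD phases 0.12–0.60, DAD phases 0.74–0.84 of the
cycle); the 0.5/1/2 Hz family; and a 100→600 nM ratiometric waveform
(K_d = 225 nM, R_min = 0.3, R_max = 6, β = 2, typical Fura-2 values).

## Known limitations

- Below ~25 FPS the sampling interval (40 ms) approaches the upstroke
  duration; the Nyquist advisory (resolution = 2.3× the sampling interval,
  92 ms at 25 FPS) is logged per run, and rise-time parameters at such
  rates are interpolation-limited.
- T_off and CD depend on the 3% redefinition by construction; compare them
  only across analyses using the same fraction.
- Touching cells are flagged, not split; kymograph-style subcellular
  analysis (sparks, waves) is out of scope.
- The pacing frequency must be supplied; it sets the onset offset, baseline
  window and adherence check.
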