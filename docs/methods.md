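# Methods

## Observation model

A paired QCM-D measurement is modelled as

```
x(n) = s(n) + c(n)   + e_x(n)        (sensor)
y(n) =        g·c(n) + e_y(n)        (reference)
```

where `s` is the analyte response (present only on the sensor), `c` a
common-mode environmental disturbance (temperature, flow, pressure,
cell stress), `g` the reference's relative response gain to that
disturbance, and `e_x`, `e_y` independent electronic noise. Nothing in
the pipeline assumes units: frequency shifts are processed in Hz,
dissipation shifts in multiples of 1e-6, and the correction is applied
to either channel identically.

The working hypothesis is that the *time derivatives* of the wavelet
coefficients of `x` and `y` are linearly correlated wherever the shared
disturbance dominates, and decorrelate wherever the analyte responds —
because the analyte signal adds derivative variance to the sensor
channel that the reference cannot explain. The correction therefore
tests for correlation locally and cancels only what is statistically
shared.

## Pipeline

1. **Decomposition.** Multi-level DWT (Mallat filter bank) of both
   channels. Default `db3` with 4 levels; at 3 samples/s the level-4
   approximation covers 0–0.094 Hz, where environmental drift lives.
   Boundary handling uses symmetric (half-point) extension — it
   minimises edge artifacts on drifting baselines; periodized extension
   is available (and is the mode under which the transform is exactly
   orthonormal). Signals whose length is not a power-of-two multiple
   are handled by the extension, never truncated. Signals shorter than
   `(filter_len − 1)·2^levels` (80 samples at defaults) are rejected
   with the minimum length in the message.

2. **Shrinkage.** Hard thresholding of detail coefficients only; the
   approximation always passes through. The default rule is the
   per-level universal threshold `λ = σ̂·√(2 ln N)` with the MAD
   estimate `σ̂ = median(|d|)/0.6745`, the standard choice when the
   noise level must be inferred from the data. An energy-fraction rule
   (zero the smallest coefficients until a configurable fraction,
   default 1%, of total energy is removed) is available; surviving
   coefficients are never shrunk, and thresholding with a fixed λ is
   idempotent.

3. **Derivative.** Forward first difference. Chosen over centred
   schemes because it is *exactly* inverted by the cumulative sum that
   step 6 uses, so the derivative/integration pair introduces no error.

4. **Windowed correlation.** Pearson R over a centred window of `w`
   coefficient-index samples (default 32), truncated — not padded — at
   the series edges with a minimum of 8 samples; the p-value comes from
   the two-sided t test with `m − 2` degrees of freedom (`m` = actual
   window size). Zero-variance windows are flagged undefined (NaN),
   never silently numeric, and route to the direct-subtraction branch.
   The window is defined in coefficient-index space because the test
   runs per decimated series: 32 indices span ~21 s at level 1 and
   ~171 s at level 4, so each band is tested on its own time scale.

5. **Cancellation.** Strictly `P(n) < α` (default α = 0.05) selects the
   projection branch `Z′ = X′ − a − b·Y′`, with `(a, b)` the
   least-squares fit of X′ on Y′ in the same window; otherwise (and at
   undefined positions) the direct difference `Z′ = X′ − Y′` is used.
   The fitted slope is what makes cancellation robust to the gain `g`;
   direct subtraction leaves `(1 − g)·c′` behind. The fit is
   re-estimated at every sample position (a per-block variant would be
   cheaper but steps across fit discontinuities).

6. **Re-integration.** Cumulative sum anchored at the sensor's own
   thresholded coefficient value at index 0, per series, so the output
   stays on the sensor's scale and `z(0) ≈ x(0)`.

7. **Reconstruction.** Inverse DWT, trimmed to the input length. The
   output keeps the sensor's sample rate and channel kind.

Degenerate inputs behave predictably: a zero reference reduces the
pipeline to wavelet denoising of the sensor; identical channels cancel
exactly (constant output); coefficient series shorter than the window
(possible only near the minimum decomposable length) fall back to
direct subtraction wholesale.

## Streaming

`StreamCorrector` runs the same batch correction over overlapping
blocks (overlap-discard): each block of `block_length` samples is
corrected independently and only its central region — margins of
`overlap` samples on each side — is emitted, so DWT boundary artifacts
and window truncation never reach the output. Because each block's
integration constant is anchored to that block's own first coefficient,
the emitted region is offset-aligned to the already-emitted samples
over the left margin before release. Defaults: overlap
`4·w·2^levels` = 2048 samples, block length 8192; the hop
(`block_length − 2·overlap`) should be a multiple of `2^levels` so that
interior coefficients of consecutive blocks fall on the same dyadic
grid.

Agreement with the batch computation is limited by re-estimation per
block: on structured signals the interior matches batch output to
better than 1e-3 of the signal range, but on noisy signals wavelet
coefficients sitting near the shrinkage threshold, and correlation
windows with p-values near α, can flip between block-wise and global
estimates, producing isolated sample-scale deviations. This is a
property of data-driven thresholds, not of the stitching.

## Stability metrics

* **Allan deviation** (non-overlapping, adjacent-bin estimator):
  `σ_y(τ) = √(½⟨(ȳ_{k+1} − ȳ_k)²⟩)` on the fractional frequency
  `y = Δf/f₀`, over bins of τ seconds. Points whose τ leaves fewer than
  two bins are omitted with a warning. An overlapping variant is
  available for smoother curves but is not the default, matching the
  adjacent-average definition.
* **Drift rate**: OLS slope of value against time, reported per hour.
  Preferred over an endpoint difference for noise robustness.
* **Baseline noise**: the trace is cut into `n_intervals` contiguous
  segments (100 by default, ~36 s each at 3 S/s for an hour record);
  each segment is linearly detrended before its SD is taken, so σ
  measures noise rather than drift — detection limits computed from it
  inherit this convention, which is stated here prominently because it
  materially changes the number on drifting baselines.
* **Sauerbrey sensitivity and IDL**: `S = −2f₀²/√(ρ_q·η_q)` in
  Hz·cm²/ng, `Δm = Δf_r/S` (valid in the rigid-film gravimetric
  regime), `IDL = 3σ/|S|`. Default quartz constants are the standard
  AT-cut values ρ_q = 2648 kg/m³ and η_q = 2.947×10¹⁰ Pa, giving
  S = −5.660 Hz·cm²/ng at 50 MHz; both constants are overridable (a
  slightly stiffer commonly quoted shear modulus, 2.95×10¹⁰ Pa, gives
  −5.657). At 50 MHz a 1 Hz noise floor corresponds to ~0.53 ng/cm².

## Synthetic data

`simulate_pair` emits `sensor = binding + c + e_x`,
`reference = g·c + e_y` with exact per-component ground truth, where
the disturbance `c` is the sum of

* a constant-rate ramp (Hz/h) and/or a piecewise-linear temperature
  trajectory (default 23 → 34 → 23 °C over the record, mapped at
  150 Hz/°C — chosen so an 11 °C excursion distorts the record by
  ~1.6 kHz, the scale a 50 MHz sensor shows under such a sweep);
* a shared random-walk wander (default step SD 0.2 Hz/sample, i.e.
  ~20 Hz of hour-scale wander at 3 S/s). The wander is part of the
  disturbance model, not a nicety: the correction detects correlated
  *fluctuations* of coefficient derivatives, and a noiseless straight
  ramp has zero within-window derivative variance — it is statistically
  invisible no matter how large. Real baselines wander; their
  interval-scale fluctuation, not their mean slope, is what the
  reference channel lets the method lock onto;
* a sawtooth flow interference (default 50 Hz peak, 60 s period,
  active 6000–6300 s in the adsorption scenario).

Binding is a sum of saturating steps `A·(1 − e^(−(t−t₀)/τ_b))` on the
sensor only; the default adsorption scenario uses −3681 Hz (τ_b 150 s)
followed by −1414 Hz, matching a first-layer deposition of
~650 ng/cm² and an overlayer of ~250 ng/cm². Noise is white Gaussian,
2 Hz SD per channel at 3 samples/s. The dissipation channel is
generated with the same structure: binding plateaus from each step's
dissipation amplitude and the disturbance scaled by 0.015 (×1e-6 per
Hz), the ratio a temperature sweep imprints on ΔD relative to Δf_r.

What the generator does *not* emulate: quadratic/cubic AT-cut
temperature-frequency curves, viscoelastic (Kanazawa) liquid loading,
compressional-wave physics, or non-stationary noise. Passing tests on
this generator therefore demonstrate the statistical mechanism of the
correction — detection and cancellation of gain-mismatched shared
components — not instrument-specific physics.

## What the correction can and cannot do

* **Drift suppression** requires the disturbance to fluctuate enough to
  be detected: with the default wander the corrected quiescent-hour
  drift falls from 200 Hz/h to a few Hz/h. Detection power scales with
  the reference's disturbance-to-noise ratio; a reference that senses
  the disturbance at half gain (g = 0.5) detects it correspondingly
  later and retains more residual drift.
* **Analyte preservation** relies on the significance test releasing
  the projection during uptake: the analyte's derivative variance
  dilutes the correlation, routing those windows to direct subtraction.
  This protection is strong for transients fast relative to the
  level-4 correlation window (~170 s at defaults): a τ_b = 150 s step
  is recovered to a few percent under the full harsh-environment
  scenario. Slow transients (τ_b ≳ 300 s) overlap the window and the
  projection's intercept absorbs part of their derivative, biasing the
  recovered amplitude low by ~10–20% under strong wander; even in the
  absence of genuine correlation the α-level false-positive floor costs
  a few percent of a slow step. Reported plateau values from slow
  uptake kinetics should therefore be treated as lower bounds, and α
  lowered if amplitude accuracy matters more than drift rejection.
* With **mixed-gain shared components** (two disturbances with
  different gains on the reference) a single fitted slope cannot cancel
  both exactly; cancellation degrades gracefully toward the dominant
  component.

## Problem sizes and tolerances

Simulated records are one hour (10 800 samples) for baseline
benchmarks and two hours (21 600) for adsorption scenarios — enough for
~680 level-4 coefficients, i.e. >20 correlation windows at the coarsest
scale. Monte-Carlo claims (drift-pass fractions, detection-limit
ordering, null calibration at 0.05 ± 0.02, Allan slope −0.5 ± 0.05) use
30–100 seeds. Perfect-reconstruction and derivative/integration
round trips are asserted at 1e-9/1e-12 relative; streaming-vs-batch
agreement at 1e-3 of signal range on structured signals. Window
truncation keeps a minimum of 8 samples so the t test retains ≥6
degrees of freedom; variances smaller than 1e-12 of the window's mean
square are treated as zero to avoid catastrophic-cancellation
artifacts.
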