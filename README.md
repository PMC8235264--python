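# qcmcorrect

Dual-resonator wavelet correction and stability metrics for QCM-D
(quartz crystal microbalance with dissipation monitoring) signals.

## The problem

High-fundamental-frequency QCM-D arrays gain mass sensitivity with the
square of the resonance frequency, but the same thin crystals become
exquisitely sensitive to everything else: temperature excursions, flow
and pressure transients, mechanical stress from the measurement cell and
electronic noise all move the resonance frequency Δf_r and the
dissipation ΔD by far more than the analyte does. When two resonators
sit millimetres apart on one substrate they experience nearly the same
environment — but with *different absolute gains* — so plain subtraction
of a reference channel (Mecea compensation) under- or over-corrects.

`qcmcorrect` implements a correction that pairs each sensing resonator
with a reference resonator and removes the shared disturbance in the
wavelet domain. For sensor x(n) and reference y(n):

1. multi-level DWT (Daubechies db3, 4 levels by default) of both
   channels into approximation and detail series X^K, Y^K;
2. hard-threshold shrinkage of the detail coefficients (per-level MAD
   universal threshold);
3. first-difference derivatives X′^K, Y′^K of every coefficient series;
4. sliding-window Pearson correlation R(n) between X′^K and Y′^K over a
   w-sample window, with a p-value P(n) from the t statistic
   t = R·√((w−2)/(1−R²));
5. where P(n) < α the corrected derivative is the residual of the local
   least-squares projection Z′ = X′ − a − b·Y′ (the slope b absorbs the
   gain mismatch); elsewhere Z′ = X′ − Y′;
6. cumulative re-integration of each corrected series;
7. inverse DWT back to the time domain.

Around the correction the package provides the standard resonator
stability metrics — Allan deviation σ_y(τ), OLS drift rate, detrended
baseline noise σ, Sauerbrey sensitivity S = −2f₀²/√(ρ_q·η_q), mass
conversion Δm = Δf_r/S and the instrument detection limit IDL = 3σ/|S| —
plus classical baselines (reference subtraction with sliding average)
and a synthetic experiment generator with exact per-component ground
truth, so every stage is testable without instrument data.

## Worked example

`examples/correct_and_recover.py` simulates a two-step protein-adsorption
run at 3 samples/s while the chamber temperature sweeps 23 → 34 → 23 °C
and the flow rate oscillates, then recovers the deposition step:

```
true first-layer step     :   -3681.0 Hz
raw sensor estimate       :   -2496.6 Hz (error 32.2%)
corrected estimate        :   -3558.5 Hz (error 3.3%)
corrected areal mass      :     628.7 ng/cm^2
```

The raw estimate is biased by a third of its value because both
resonators ride the temperature excursion; the corrected trace recovers
the known −3681 Hz step to a few percent and converts to areal mass
through the Sauerbrey relation (S = −5.66 Hz·cm²/ng at 50 MHz, so
1 Hz ≈ 0.18 ng/cm²).

`examples/stability_metrics.py` runs the quiescent-baseline benchmark
(one hour, 200 Hz/h common drift, 2 Hz noise) and prints, per treatment:

```
method    drift Hz/h  sigma Hz  IDL ng/cm^2
raw            185.5     2.045        1.084
mecea          -37.1     0.574        0.304
dwt              0.3     0.515        0.273
```

together with the Allan deviation curves (the corrected arm is the most
stable at every integration time against the raw signal). The other
examples cover CSV export/import and real-time block streaming.

A thin CLI wraps the same library calls:

```sh
qcmcorrect simulate --scenario adsorption --seed 0 traces.csv
qcmcorrect correct --method dwt traces.csv corrected.csv
qcmcorrect metrics corrected.csv
```

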