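"""Recover a protein-adsorption curve from a harsh-environment recording.

Simulates a two-step adsorption experiment (neutravidin-scale first layer,
smaller overlayer) at 3 samples/s while the chamber temperature sweeps
23 -> 34 -> 23 degC and the flow rate oscillates late in the run, then
removes the shared disturbance with the dual-resonator wavelet correction
and converts the recovered plateau to an areal mass density.
"""

import numpy as np

from qcmcorrect import (
    SensorSpec,
    adsorption_config,
    correct_pair,
    mass_from_frequency,
    simulate_pair,
)

pair, truth = simulate_pair(adsorption_config(seed=0))
corrected = correct_pair(pair)

t = pair.sensor.times
baseline = slice(*np.searchsorted(t, (300.0, 590.0)))
plateau = slice(*np.searchsorted(t, (2500.0, 3500.0)))

raw_step = pair.sensor.values[plateau].mean() - pair.sensor.values[baseline].mean()
cor_step = corrected.values[plateau].mean() - corrected.values[baseline].mean()
true_step = truth.binding_sensor[plateau].mean() - truth.binding_sensor[baseline].mean()

spec = SensorSpec(f0=50e6)
print(f"true first-layer step     : {true_step:9.1f} Hz")
print(f"raw sensor estimate       : {raw_step:9.1f} Hz "
      f"(error {100 * abs(raw_step - true_step) / abs(true_step):.1f}%)")
print(f"corrected estimate        : {cor_step:9.1f} Hz "
      f"(error {100 * abs(cor_step - true_step) / abs(true_step):.1f}%)")
print(f"corrected areal mass      : {abs(mass_from_frequency(cor_step, spec)):9.1f} ng/cm^2")

# The raw step is biased by the temperature excursion that both resonators
# share; the corrected step recovers the known deposition amplitude to a
# few percent, and the Sauerbrey conversion turns it into ng/cm^2.
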