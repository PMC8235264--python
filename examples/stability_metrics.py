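"""Quantify the stability gain on a quiescent baseline hour.

Simulates one hour of baseline (200 Hz/h common-mode drift, shared
wander, 2 Hz electronic noise per channel), applies three treatments —
none, classical reference subtraction with a 16-sample sliding average,
and the wavelet correction — then reports drift rate, baseline noise,
detection limit and the Allan deviation curve for each.
"""

from qcmcorrect import (
    SensorSpec,
    allan_deviation,
    baseline_noise,
    correct_pair,
    drift_rate,
    idl,
    mecea_filtered,
    quiescent_config,
    raw_passthrough,
    simulate_pair,
)
from qcmcorrect.metrics import default_taus

spec = SensorSpec(f0=50e6)
pair, _ = simulate_pair(quiescent_config(seed=1))

arms = {
    "raw": raw_passthrough(pair),
    "mecea": mecea_filtered(pair),
    "dwt": correct_pair(pair),
}

print(f"{'method':8s} {'drift Hz/h':>11s} {'sigma Hz':>9s} {'IDL ng/cm^2':>12s}")
for name, trace in arms.items():
    noise = baseline_noise(trace, n_intervals=100)
    print(f"{name:8s} {drift_rate(trace):11.1f} {noise.sigma:9.3f} "
          f"{idl(noise.sigma, spec):12.3f}")

taus = default_taus(pair.sensor)
curves = {name: allan_deviation(tr, spec, taus) for name, tr in arms.items()}
print("\ntau_s      ADEV(raw)    ADEV(mecea)  ADEV(dwt)")
for i, tau in enumerate(curves["raw"].taus):
    print(f"{tau:8.2f} {curves['raw'].adev[i]:12.3e} "
          f"{curves['mecea'].adev[i]:12.3e} {curves['dwt'].adev[i]:12.3e}")

# Lower is better everywhere: the corrected arm suppresses both the
# drift (long-tau stability) and the high-frequency noise (short-tau
# stability), which is what drives its order-of-magnitude IDL advantage.
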