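"""Generate a synthetic paired recording and write it as a dialect CSV.

The file carries a time column plus sensor/reference columns (and,
optionally, the exact ground-truth components), so any stage of the
package — or an external tool — can be exercised without instrument
data. The same scenario is reachable from the shell:

    qcmcorrect simulate --scenario adsorption --seed 0 --with-truth out.csv
"""

from pathlib import Path

from qcmcorrect import adsorption_config, read_traces, simulate_pair, write_traces

out = Path("scratch_example_traces.csv")
pair, truth = simulate_pair(adsorption_config(seed=0))
write_traces([pair], out, truth=truth)

(back,) = read_traces(out)
print(f"wrote {out} with {len(pair)} samples at {pair.sample_rate:g} S/s")
print(f"round-trip intact: {max(abs(back.sensor.values - pair.sensor.values)) < 1e-9}")
print(f"sensor span  : {pair.sensor.values.min():9.1f} .. {pair.sensor.values.max():7.1f} Hz")
print(f"reference span: {pair.reference.values.min():8.1f} .. {pair.reference.values.max():7.1f} Hz")
out.unlink()  # keep the working tree clean

# The sensor trace mixes the binding transient with the shared temperature
# and flow disturbances; the reference sees only the (gain-scaled)
# disturbances, which is exactly the structure the correction exploits.
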