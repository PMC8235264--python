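"""Run the correction as a real-time block processor.

Feeds a paired recording chunk-by-chunk (as an acquisition loop would)
through the overlap-discard streaming front end and checks the emitted
samples against the one-shot batch result.
"""

import numpy as np

from qcmcorrect import correct_pair
from qcmcorrect.correction import StreamCorrector
from qcmcorrect.signal_model import PairedRecord, ResonatorTrace

# structured pair: shared drift + oscillations (reference gain 1.2) and a
# saturating uptake on the sensor only
n = 10800
t = np.arange(n) / 3.0
dist = 200.0 * t / 3600.0 + 15.0 * np.sin(2 * np.pi * t / 97.0)
bind = np.where(t > 600.0, -3681.0 * (1.0 - np.exp(-np.clip(t - 600.0, 0.0, None) / 150.0)), 0.0)
pair = PairedRecord(ResonatorTrace(bind + dist, 3.0), ResonatorTrace(1.2 * dist, 3.0))
x, y = pair.sensor.values, pair.reference.values

sc = StreamCorrector(block_length=8192, overlap=2048, sample_rate=pair.sample_rate)
emitted = []
for i in range(0, x.size, 512):          # 512 samples ~ 171 s of acquisition
    out = sc.push(x[i : i + 512], y[i : i + 512])
    if out.size:
        print(f"after {i + 512:6d} samples in: emitted {out.size:5d} corrected samples")
        emitted.append(out)
emitted.append(sc.finish())
streamed = np.concatenate(emitted)

batch = correct_pair(pair).values
dev = np.max(np.abs(streamed - batch)) / np.ptp(batch)
print(f"total emitted: {streamed.size} of {x.size}")
print(f"max deviation from batch: {dev:.2e} of the signal range")

# Latency is bounded by the block length. On structured signals the
# emitted stream matches the batch result to well under 1e-3 of the
# signal range; on noisy signals, borderline wavelet coefficients can
# flip as thresholds are re-estimated per block (see docs/methods.md).
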