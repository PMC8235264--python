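"""Comparator methods for benchmarking the wavelet correction.

``mecea_filtered`` is the classical reference-subtraction compensation
(sensor minus reference) followed by a short sliding average to tame the
doubled high-frequency noise; ``raw_passthrough`` is the uncorrected
sensor signal. Both serve as benchmark arms next to ``correct_pair``.
"""

from __future__ import annotations

import numpy as np

from .signal_model import PairedRecord, ResonatorTrace

__all__ = ["mecea_filtered", "raw_passthrough", "moving_average"]


def moving_average(values: np.ndarray, window: int, centered: bool = True) -> np.ndarray:
    """Sliding mean with edge truncation (no padding is fabricated).

    ``centered=False`` gives a trailing (causal) window instead.
    """
    v = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window == 1:
        return v.copy()
    n = v.size
    idx = np.arange(n)
    lo = idx - (window - 1) // 2 if centered else idx - (window - 1)
    starts = np.clip(lo, 0, None)
    ends = np.clip(lo + window, None, n) if centered else idx + 1
    cs = np.zeros(n + 1)
    np.cumsum(v, out=cs[1:])
    return (cs[ends] - cs[starts]) / (ends - starts)


def mecea_filtered(pair: PairedRecord, window: int = 16, centered: bool = True) -> ResonatorTrace:
    """Reference compensation: sliding average of (sensor - reference).

    The 16-sample default matches the benchmark configuration used for
    comparison against the wavelet method. Linear in its inputs.
    """
    diff = pair.sensor.values - pair.reference.values
    out = moving_average(diff, window, centered=centered)
    return pair.sensor.with_values(out, label=f"{pair.sensor.label or 'sensor'}_mecea")


def raw_passthrough(pair: PairedRecord) -> ResonatorTrace:
    """The uncorrected sensor trace (benchmark arm)."""
    return pair.sensor.with_values(pair.sensor.values.copy())
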