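import numpy as np
import pytest

from qcmcorrect.signal_model import CorrectionParams, PairedRecord, ResonatorTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return CorrectionParams()


@pytest.fixture
def make_trace():
    def _make(values, rate=3.0, kind="frequency", label=""):
        return ResonatorTrace(np.asarray(values, dtype=float), rate, kind, label)

    return _make


@pytest.fixture
def make_pair(make_trace):
    def _make(sensor_values, reference_values, rate=3.0, kind="frequency"):
        return PairedRecord(
            make_trace(sensor_values, rate, kind, "sensor"),
            make_trace(reference_values, rate, kind, "reference"),
        )

    return _make


@pytest.fixture
def structured_pair(make_pair):
    """Deterministic noise-free pair: common drift + oscillations shared by
    both channels (reference gain 1.2), a saturating uptake transient on
    the sensor only."""
    n = 10800
    t = np.arange(n) / 3.0
    dist = (
        200.0 * t / 3600.0
        + 15.0 * np.sin(2 * np.pi * t / 97.0)
        + 8.0 * np.sin(2 * np.pi * t / 211.0)
    )
    bind = np.where(
        t > 600.0, -3681.0 * (1.0 - np.exp(-np.clip(t - 600.0, 0.0, None) / 150.0)), 0.0
    )
    return make_pair(bind + dist, 1.2 * dist)
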