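"""Core data types for dual-resonator QCM-D signal processing.

A measurement consists of uniformly sampled resonance-frequency shift (Hz)
or dissipation shift (dimensionless, reported in units of 1e-6) traces.
Traces come in sensor/reference pairs: the *sensor* resonator is exposed to
the sample while the *reference* sees only the shared environment
(temperature, flow, mechanical stress, electronics), which is what the
correction algorithm removes.

This module holds containers and validation only; algorithms live in
:mod:`qcmcorrect.wavelet_engine`, :mod:`qcmcorrect.correction`,
:mod:`qcmcorrect.baselines` and :mod:`qcmcorrect.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "ChannelKind",
    "ResonatorTrace",
    "PairedRecord",
    "SensorSpec",
    "CorrectionParams",
]

ChannelKind = Literal["frequency", "dissipation"]

#: AT-cut quartz density, kg/m^3.
QUARTZ_DENSITY = 2648.0
#: AT-cut quartz shear modulus, Pa.
QUARTZ_SHEAR_MODULUS = 2.947e10


@dataclass(frozen=True)
class ResonatorTrace:
    """One uniformly sampled resonator signal.

    Parameters
    ----------
    values
        Samples; Hz for a frequency-shift channel, units of 1e-6 for a
        dissipation-shift channel. Must be finite.
    sample_rate
        Samples per second; must be positive.
    channel_kind
        ``"frequency"`` or ``"dissipation"``.
    label
        Free-text identifier (e.g. ``"sensor"``).
    """

    values: np.ndarray
    sample_rate: float
    channel_kind: ChannelKind = "frequency"
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("trace values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise ValueError(f"trace contains non-finite value at index {bad}")
        if not (self.sample_rate > 0):
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.channel_kind not in ("frequency", "dissipation"):
            raise ValueError(f"unknown channel_kind {self.channel_kind!r}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Span of the time grid in seconds, ``(n - 1) / sample_rate``."""
        return (len(self) - 1) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Time stamps in seconds, starting at 0."""
        return np.arange(len(self)) / self.sample_rate

    def with_values(self, values: np.ndarray, label: str | None = None) -> "ResonatorTrace":
        """Copy of this trace with new samples (same rate and kind)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)


@dataclass(frozen=True)
class PairedRecord:
    """A sensor trace and its co-located reference trace.

    Both traces must have equal length, equal sample rate and equal
    channel kind; mismatches are rejected at construction.
    """

    sensor: ResonatorTrace
    reference: ResonatorTrace

    def __post_init__(self) -> None:
        s, r = self.sensor, self.reference
        if len(s) != len(r):
            raise ValueError(
                f"sensor and reference lengths differ ({len(s)} vs {len(r)})"
            )
        if not np.isclose(s.sample_rate, r.sample_rate, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"sensor and reference sample rates differ "
                f"({s.sample_rate} vs {r.sample_rate})"
            )
        if s.channel_kind != r.channel_kind:
            raise ValueError(
                f"sensor and reference channel kinds differ "
                f"({s.channel_kind} vs {r.channel_kind})"
            )

    def __len__(self) -> int:
        return len(self.sensor)

    @property
    def sample_rate(self) -> float:
        return self.sensor.sample_rate

    @property
    def channel_kind(self) -> ChannelKind:
        return self.sensor.channel_kind


@dataclass(frozen=True)
class SensorSpec:
    """Physical description of an AT-cut quartz resonator.

    Defaults are the standard AT-cut constants; both are overridable for
    non-standard cuts. ``f0`` is the fundamental resonance frequency in Hz
    (50 MHz for the high-fundamental-frequency sensors this package
    targets).
    """

    f0: float
    rho_q: float = QUARTZ_DENSITY
    eta_q: float = QUARTZ_SHEAR_MODULUS

    def __post_init__(self) -> None:
        for name in ("f0", "rho_q", "eta_q"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


ThresholdRule = Literal["universal", "energy", "none"]


@dataclass(frozen=True)
class CorrectionParams:
    """Tunable parameters of the dual-resonator correction.

    Attributes
    ----------
    wavelet
        Wavelet family identifier understood by PyWavelets; default
        ``"db3"`` (Daubechies, three vanishing moments).
    levels
        Number of decomposition levels of the Mallat tree (default 4).
    window
        Sliding-window length ``w``, in coefficient-index samples, used
        for the Pearson correlation and the local linear fit. Correlation
        and projection operate on the decimated coefficient series, so the
        window is expressed there, not in time-domain samples. Default 32.
    alpha
        Significance level on the correlation p-value deciding between
        projection cancellation and direct subtraction. Default 0.05.
    threshold_rule
        Detail-coefficient shrinkage policy: ``"universal"`` (per-level
        MAD-based universal threshold, the default), ``"energy"``
        (cumulative energy-fraction rule) or ``"none"``.
    energy_fraction
        Fraction of total coefficient energy zeroed by the ``"energy"``
        rule (default 0.01).
    extension_mode
        Boundary extension of the filter bank; PyWavelets mode name,
        default ``"symmetric"``.
    """

    wavelet: str = "db3"
    levels: int = 4
    window: int = 32
    alpha: float = 0.05
    threshold_rule: ThresholdRule = "universal"
    energy_fraction: float = 0.01
    extension_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.window < 8:
            raise ValueError(
                f"window must be >= 8 so that w-2 degrees of freedom is "
                f"meaningful, got {self.window}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.threshold_rule not in ("universal", "energy", "none"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if not (0.0 <= self.energy_fraction < 1.0):
            raise ValueError(
                f"energy_fraction must lie in [0, 1), got {self.energy_fraction}"
            )
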