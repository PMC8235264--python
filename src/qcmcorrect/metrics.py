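"""Stability and sensitivity metrics for resonator traces.

* Allan deviation of fractional frequency vs integration time (the
  standard resonator-stability measure);
* baseline drift rate from an ordinary least-squares line, in Hz/hour;
* baseline noise sigma from per-interval detrended standard deviations;
* Sauerbrey mass sensitivity S = -2 f0^2 / sqrt(rho_q eta_q) and the
  gravimetric frequency-to-mass conversion;
* instrument detection limit IDL = 3 sigma / |S|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_model import ResonatorTrace, SensorSpec

__all__ = [
    "AllanCurve",
    "allan_deviation",
    "default_taus",
    "drift_rate",
    "sauerbrey_sensitivity",
    "mass_from_frequency",
    "BaselineNoise",
    "baseline_noise",
    "idl",
]

#: (Hz * m^2 / kg) -> (Hz * cm^2 / ng)
_SI_TO_HZ_CM2_PER_NG = 1e-8


@dataclass(frozen=True)
class AllanCurve:
    """Allan deviation curve: sigma_y(tau) with pair counts per point."""

    taus: np.ndarray
    adev: np.ndarray
    n_terms: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be strictly increasing")
        if np.any(self.adev < 0) or np.any(self.n_terms < 1):
            raise ValueError("invalid Allan curve values")


def default_taus(trace: ResonatorTrace, points_per_decade: int = 3) -> np.ndarray:
    """Logarithmically spaced integration times from one sample interval
    up to a quarter of the record length, snapped to integer multiples of
    the sample interval."""
    dt = 1.0 / trace.sample_rate
    max_k = max(len(trace) // 4, 1)
    ks = np.unique(
        np.round(
            np.logspace(0, np.log10(max_k), num=max(int(np.log10(max_k) * points_per_decade) + 1, 2))
        ).astype(int)
    )
    return ks[ks >= 1] * dt


def allan_deviation(
    trace: ResonatorTrace,
    spec: SensorSpec,
    taus: np.ndarray | None = None,
    overlapping: bool = False,
) -> AllanCurve:
    """Allan deviation of the fractional frequency y = delta_f / f0.

    The non-overlapping (standard) two-sample estimator is the default:
    sigma_y(tau) = sqrt( 0.5 < (ybar_{n+1} - ybar_n)^2 > ) over adjacent
    non-overlapping bins of tau seconds. ``overlapping=True`` uses every
    bin start for a smoother curve.

    Integration times that do not leave at least two bins are omitted
    with a warning.
    """
    if trace.channel_kind != "frequency":
        raise ValueError("Allan deviation is defined on a frequency-shift channel")
    if taus is None:
        taus = default_taus(trace)
    dt = 1.0 / trace.sample_rate
    y = trace.values / spec.f0
    out_t, out_a, out_n = [], [], []
    for tau in np.asarray(taus, dtype=float):
        k = int(round(tau / dt))
        if k < 1 or not np.isclose(k * dt, tau, rtol=1e-6):
            raise ValueError(f"tau {tau} is not a multiple of the sample interval {dt}")
        nbins = y.size // k
        if nbins < 2:
            warnings.warn(f"tau {tau:g}s too large for trace; point omitted")
            continue
        if overlapping:
            csum = np.concatenate([[0.0], np.cumsum(y)])
            means = (csum[k:] - csum[:-k]) / k  # mean over every window start
            d = means[k:] - means[:-k]
        else:
            means = y[: nbins * k].reshape(nbins, k).mean(axis=1)
            d = np.diff(means)
        out_t.append(k * dt)
        out_a.append(float(np.sqrt(0.5 * np.mean(d * d))))
        out_n.append(d.size)
    return AllanCurve(
        taus=np.asarray(out_t), adev=np.asarray(out_a), n_terms=np.asarray(out_n)
    )


def drift_rate(trace: ResonatorTrace) -> float:
    """Baseline drift as the OLS slope of value vs time, in (units)/hour.

    OLS is used rather than an endpoint difference so the estimate is
    robust to noise.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to estimate drift")
    t = trace.times
    slope = np.polyfit(t, trace.values, 1)[0]  # units per second
    return float(slope * 3600.0)


def sauerbrey_sensitivity(spec: SensorSpec) -> float:
    """Sauerbrey mass sensitivity S = -2 f0^2 / sqrt(rho_q eta_q), in
    Hz cm^2/ng.

    Negative: mass uptake lowers the resonance frequency. Scales with
    f0^2, which is why high-fundamental-frequency sensors gain
    sensitivity.
    """
    s_si = -2.0 * spec.f0**2 / np.sqrt(spec.rho_q * spec.eta_q)
    return float(s_si * _SI_TO_HZ_CM2_PER_NG)


def mass_from_frequency(delta_f: float, spec: SensorSpec) -> float:
    """Areal mass density (ng/cm^2) from a frequency shift (Hz).

    Valid in the gravimetric (rigid, thin film) regime where the
    Sauerbrey relation holds; a negative frequency shift maps to a
    positive adsorbed mass.
    """
    return float(delta_f / sauerbrey_sensitivity(spec))


@dataclass(frozen=True)
class BaselineNoise:
    """Baseline noise summary: mean per-interval detrended SD and its
    spread across intervals."""

    sigma: float
    spread: float
    per_interval: np.ndarray


def baseline_noise(trace: ResonatorTrace, n_intervals: int = 100) -> BaselineNoise:
    """System noise sigma from a quiescent baseline recording.

    The trace is split into ``n_intervals`` equal contiguous segments;
    each segment is linearly detrended (so slow drift does not inflate
    the noise estimate) and its sample standard deviation taken. ``sigma``
    is the mean over segments, ``spread`` their standard deviation (error
    bars). Detection limits computed from sigma therefore quantify noise,
    not drift.
    """
    v = trace.values
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    seg = v.size // n_intervals
    if seg < 2:
        raise ValueError(
            f"trace of {v.size} samples too short for {n_intervals} intervals"
        )
    sds = np.empty(n_intervals)
    x = np.arange(seg)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    for i in range(n_intervals):
        w = v[i * seg : (i + 1) * seg]
        slope = float(np.dot(xc, w - w.mean())) / denom
        resid = w - w.mean() - slope * xc
        sds[i] = np.std(resid, ddof=2)  # two parameters fitted
    return BaselineNoise(
        sigma=float(np.mean(sds)), spread=float(np.std(sds)), per_interval=sds
    )


def idl(sigma: float, spec: SensorSpec) -> float:
    """Instrument detection limit, 3 sigma / |S|, in ng/cm^2.

    The minimum areal mass distinguishable from baseline noise sigma (Hz)
    given the Sauerbrey sensitivity of the resonator.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(3.0 * sigma / abs(sauerbrey_sensitivity(spec)))
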