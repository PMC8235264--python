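"""Multi-level DWT and wavelet-shrinkage hard thresholding.

The forward/inverse transform is the Mallat filter-bank decomposition
(quadrature-mirror filters, decimation by 2 per level) as implemented by
PyWavelets. Shrinkage zeroes detail coefficients that carry no significant
signal energy; approximation coefficients are never thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

from .signal_model import CorrectionParams, ResonatorTrace

__all__ = [
    "CoefficientSet",
    "min_length",
    "dwt_decompose",
    "idwt_reconstruct",
    "hard_threshold",
    "universal_thresholds",
]


@dataclass(frozen=True)
class CoefficientSet:
    """Multi-level DWT expansion {A, D1..Dq} of one trace.

    ``details[0]`` is D1, the finest band; ``details[-1]`` is Dq, the
    coarsest. ``approximation`` is the level-q approximation series A.
    """

    approximation: np.ndarray
    details: tuple[np.ndarray, ...]
    wavelet: str
    levels: int
    original_length: int
    extension_mode: str
    sample_rate: float = 1.0
    channel_kind: str = "frequency"
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.details) != self.levels:
            raise ValueError(
                f"expected {self.levels} detail series, got {len(self.details)}"
            )
        expected = _expected_lengths(
            self.original_length, self.wavelet, self.levels, self.extension_mode
        )
        got = [len(self.approximation)] + [len(d) for d in self.details[::-1]]
        if got != expected:
            raise ValueError(
                f"coefficient lengths {got} inconsistent with original_length "
                f"{self.original_length} (expected {expected})"
            )

    def series(self) -> list[tuple[str, np.ndarray]]:
        """All coefficient series in (name, values) form: A, D1..Dq."""
        out = [("A", self.approximation)]
        out += [(f"D{i + 1}", d) for i, d in enumerate(self.details)]
        return out

    def _to_pywt(self) -> list[np.ndarray]:
        # pywt ordering: [cA_q, cD_q, ..., cD_1]
        return [np.asarray(self.approximation)] + [
            np.asarray(d) for d in self.details[::-1]
        ]


def _expected_lengths(n: int, wavelet: str, levels: int, mode: str) -> list[int]:
    w = pywt.Wavelet(wavelet)
    lengths = []
    ln = n
    for _ in range(levels):
        ln = pywt.dwt_coeff_len(ln, w.dec_len, mode)
        lengths.append(ln)
    # [len(cA_q), len(cD_q), ..., len(cD_1)]
    return [lengths[-1]] + lengths[::-1]


def min_length(wavelet: str = "db3", levels: int = 4) -> int:
    """Shortest signal that supports ``levels`` decomposition levels.

    Derived from the PyWavelets maximum-useful-level rule: the filter
    support at the deepest level must fit inside the signal.
    """
    filt = pywt.Wavelet(wavelet).dec_len
    return (filt - 1) * 2**levels


def dwt_decompose(trace: ResonatorTrace, params: CorrectionParams) -> CoefficientSet:
    """Forward multi-level DWT of a trace.

    Signals whose length is not a multiple of ``2**levels`` are handled by
    the boundary-extension mode, never by truncation.

    Raises
    ------
    ValueError
        If the trace is shorter than :func:`min_length` for the requested
        wavelet/levels.
    """
    n = len(trace)
    need = min_length(params.wavelet, params.levels)
    if n < need:
        raise ValueError(
            f"signal of length {n} too short for {params.levels} "
            f"{params.wavelet} levels; need at least {need} samples"
        )
    coeffs = pywt.wavedec(
        trace.values, params.wavelet, mode=params.extension_mode, level=params.levels
    )
    approx, *details_coarse_to_fine = coeffs
    return CoefficientSet(
        approximation=approx,
        details=tuple(details_coarse_to_fine[::-1]),
        wavelet=params.wavelet,
        levels=params.levels,
        original_length=n,
        extension_mode=params.extension_mode,
        sample_rate=trace.sample_rate,
        channel_kind=trace.channel_kind,
        label=trace.label,
    )


def idwt_reconstruct(coeffs: CoefficientSet) -> ResonatorTrace:
    """Inverse multi-level DWT back to a time-domain trace.

    Returns a trace of ``original_length`` samples (the filter bank may
    internally produce one extra sample which is trimmed).
    """
    rec = pywt.waverec(coeffs._to_pywt(), coeffs.wavelet, mode=coeffs.extension_mode)
    rec = rec[: coeffs.original_length]
    return ResonatorTrace(
        values=rec,
        sample_rate=coeffs.sample_rate,
        channel_kind=coeffs.channel_kind,  # type: ignore[arg-type]
        label=coeffs.label,
    )


def universal_thresholds(coeffs: CoefficientSet) -> list[float]:
    """Per-level universal threshold for each detail series (D1..Dq).

    lambda = sigma_hat * sqrt(2 ln N) with sigma_hat the MAD estimate
    median(|d|)/0.6745 computed on that level's coefficients.
    """
    out = []
    for d in coeffs.details:
        n = len(d)
        if n == 0:
            out.append(0.0)
            continue
        sigma = float(np.median(np.abs(d))) / 0.6745
        out.append(sigma * np.sqrt(2.0 * np.log(max(n, 2))))
    return out


def _energy_mask(coeffs: CoefficientSet, fraction: float) -> list[np.ndarray]:
    """Masks (True = keep) zeroing the smallest detail coefficients whose
    cumulative squared magnitude stays below ``fraction`` of the total
    coefficient energy (approximation included in the total)."""
    total = float(np.sum(coeffs.approximation**2)) + sum(
        float(np.sum(d**2)) for d in coeffs.details
    )
    flat = np.concatenate([d for d in coeffs.details]) if coeffs.details else np.empty(0)
    if flat.size == 0 or total == 0.0:
        return [np.ones(len(d), dtype=bool) for d in coeffs.details]
    order = np.argsort(flat**2, kind="stable")
    cum = np.cumsum(flat[order] ** 2)
    drop_flat = np.zeros(flat.size, dtype=bool)
    drop_flat[order] = cum <= fraction * total
    masks = []
    pos = 0
    for d in coeffs.details:
        masks.append(~drop_flat[pos : pos + len(d)])
        pos += len(d)
    return masks


def hard_threshold(
    coeffs: CoefficientSet,
    rule: str | None = None,
    *,
    value: float | None = None,
    energy_fraction: float = 0.01,
) -> CoefficientSet:
    """Hard-threshold the detail coefficients of a decomposition.

    A detail coefficient ``d`` becomes 0 if ``|d| < lambda`` and is kept
    unchanged otherwise (never shrunk). The approximation series passes
    through untouched.

    Parameters
    ----------
    rule
        ``"universal"`` (default): per-level MAD universal threshold;
        ``"energy"``: zero coefficients whose cumulative squared magnitude
        is below ``energy_fraction`` of total energy; ``"none"``: identity.
    value
        Explicit threshold applied to every detail level; overrides
        ``rule`` when given.
    """
    if value is not None:
        lambdas = [float(value)] * coeffs.levels
        new_details = tuple(
            np.where(np.abs(d) < lam, 0.0, d) for d, lam in zip(coeffs.details, lambdas)
        )
    else:
        rule = rule or "universal"
        if rule == "none":
            return coeffs
        if rule == "universal":
            lambdas = universal_thresholds(coeffs)
            new_details = tuple(
                np.where(np.abs(d) < lam, 0.0, d)
                for d, lam in zip(coeffs.details, lambdas)
            )
        elif rule == "energy":
            masks = _energy_mask(coeffs, energy_fraction)
            new_details = tuple(
                np.where(m, d, 0.0) for d, m in zip(coeffs.details, masks)
            )
        else:
            raise ValueError(f"unknown threshold rule {rule!r}")
    return replace(coeffs, details=new_details)


def threshold_for_params(coeffs: CoefficientSet, params: CorrectionParams) -> CoefficientSet:
    """Apply the shrinkage policy selected by ``params``."""
    return hard_threshold(
        coeffs, params.threshold_rule, energy_fraction=params.energy_fraction
    )
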