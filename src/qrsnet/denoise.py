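"""Wavelet decomposition, coefficient-zeroing denoise, and filter metrics.

The denoising rule: decompose to 8 levels, zero the level-1 and level-2
detail coefficients (high-frequency noise) and the level-8 approximation
(baseline drift), and reconstruct.  The detail bands at levels 3-5 carry
most of the QRS energy and are reused by the R-wave enhancement stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .types import InvalidArgumentError

#: wavelet bases the denoiser is validated against
SUPPORTED_BASES = ("haar", "bior2.6", "db4", "db6", "db8", "sym2", "sym4", "sym6", "sym8")

DEFAULT_BASIS = "sym2"
DEFAULT_LEVELS = 8
#: boundary extension used for every transform (a config knob, not a constant of the method)
DEFAULT_MODE = "symmetric"


class DecompositionDepthError(ValueError):
    """Signal too short for the requested decomposition depth."""


@dataclass
class WaveletDecomposition:
    """Multi-level DWT coefficients plus bookkeeping for exact reconstruction.

    ``coeffs`` is the pywt layout ``[a_L, d_L, ..., d_1]``.
    """

    basis: str
    coeffs: list
    original_length: int
    mode: str = DEFAULT_MODE

    @property
    def levels(self) -> int:
        return len(self.coeffs) - 1

    @property
    def approx(self) -> np.ndarray:
        return self.coeffs[0]

    def detail(self, level: int) -> np.ndarray:
        """Detail coefficients at ``level`` (1 = finest)."""
        if not 1 <= level <= self.levels:
            raise InvalidArgumentError(f"level must be in 1..{self.levels}, got {level}")
        return self.coeffs[len(self.coeffs) - level]


def decompose(signal, basis: str = DEFAULT_BASIS, levels: int = DEFAULT_LEVELS,
              mode: str = DEFAULT_MODE) -> WaveletDecomposition:
    """Multi-level discrete wavelet transform.

    Raises :class:`DecompositionDepthError` when the signal is shorter than
    ``2**levels`` samples.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("signal must be 1-d")
    if x.size < 2**levels:
        raise DecompositionDepthError(
            f"signal of {x.size} samples too short for a {levels}-level decomposition "
            f"(needs >= {2**levels})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, basis, mode=mode, level=levels)
    return WaveletDecomposition(basis=basis, coeffs=list(coeffs), original_length=x.size, mode=mode)


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse transform, trimmed to the original signal length."""
    y = pywt.waverec(decomp.coeffs, decomp.basis, mode=decomp.mode)
    return y[: decomp.original_length]


def band_signal(decomp: WaveletDecomposition, level: int) -> np.ndarray:
    """Single-band reconstruction: only detail level ``level`` kept (0 = approx)."""
    coeffs = [np.zeros_like(c) for c in decomp.coeffs]
    if level == 0:
        coeffs[0] = decomp.coeffs[0]
    else:
        if not 1 <= level <= decomp.levels:
            raise InvalidArgumentError(f"level must be in 0..{decomp.levels}, got {level}")
        pos = len(decomp.coeffs) - level
        coeffs[pos] = decomp.coeffs[pos]
    y = pywt.waverec(coeffs, decomp.basis, mode=decomp.mode)
    return y[: decomp.original_length]


def denoise(signal, basis: str = DEFAULT_BASIS, levels: int = DEFAULT_LEVELS,
            mode: str = DEFAULT_MODE) -> np.ndarray:
    """Zero d1, d2 and the deepest approximation, then reconstruct.

    Output length equals input length.
    """
    decomp = decompose(signal, basis=basis, levels=levels, mode=mode)
    coeffs = list(decomp.coeffs)
    coeffs[0] = np.zeros_like(coeffs[0])  # a_L: baseline drift
    coeffs[-1] = np.zeros_like(coeffs[-1])  # d1: high-frequency noise
    coeffs[-2] = np.zeros_like(coeffs[-2])  # d2
    y = pywt.waverec(coeffs, basis, mode=mode)
    return y[: decomp.original_length]


@dataclass(frozen=True)
class FilterMetrics:
    """Filter-quality metrics: ``snr`` (dimensionless ratio) and ``mse`` (mV^2)."""

    snr: float
    mse: float


def filter_metrics(reference, filtered, snr_mode: str = "ratio") -> FilterMetrics:
    """MSE and SNR between a reference trace and a filtered trace.

    ``snr_mode="ratio"`` : power(filtered) / power(reference), unity when the
    filter preserves the signal's energy.  ``snr_mode="db"`` :
    ``10 log10(sum(ref^2) / sum((ref - filtered)^2))``.
    """
    ref = np.asarray(reference, dtype=float)
    fil = np.asarray(filtered, dtype=float)
    if ref.shape != fil.shape:
        raise InvalidArgumentError(f"length mismatch: {ref.shape} vs {fil.shape}")
    mse = float(np.mean((ref - fil) ** 2))
    if snr_mode == "ratio":
        denom = float(np.sum(ref**2))
        snr = float(np.sum(fil**2)) / denom if denom > 0 else np.inf
    elif snr_mode == "db":
        err = float(np.sum((ref - fil) ** 2))
        snr = 10.0 * np.log10(np.sum(ref**2) / err) if err > 0 else np.inf
    else:
        raise InvalidArgumentError(f"unknown snr_mode {snr_mode!r}")
    return FilterMetrics(snr=snr, mse=mse)
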