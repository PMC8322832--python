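"""R-wave enhancement, adaptive-threshold peak picking, and P/Q/S/T location.

The enhancement combines the detail bands at decomposition levels 3-5
(each reconstructed back to signal length) elementwise:

    e1  = d3 + d4 + d5
    e2  = d4 * (2*d3 + d5)
    e11 = e1 * e2

which concentrates positive energy at the R wave while the Q/S deflections
largely cancel.  R peaks are then picked with an adaptive threshold: a
fixed window of 215 samples (step = width) whose local maximum sets the
threshold at 60% of itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .denoise import WaveletDecomposition, band_signal
from .types import FiducialSet, InvalidArgumentError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 215  # samples (~0.6 s at 360 Hz)
DEFAULT_FRAC = 0.6
DEFAULT_REFRACTORY = 72  # samples (200 ms at 360 Hz)
DEFAULT_MATCH_TOL = 54  # samples (150 ms at 360 Hz)
# samples searched around the e11 extremum for the raw-signal R peak; the
# product transform can displace its extremum by several tens of samples for
# wide QRS complexes, so the radius must comfortably exceed that shift while
# staying below the minimum RR interval
R_REFINE_RADIUS = 60

# P/Q/S/T search windows in seconds relative to the refined R (or S) peak
Q_WINDOW_S = 0.10
S_WINDOW_S = 0.10
P_WINDOW_S = 0.20
T_START_S = 0.05
T_END_S = 0.45


class UndefinedMetricError(ZeroDivisionError):
    """Se or P has an empty denominator."""


@dataclass
class EnhancedSignal:
    """The four-operations products, sample-aligned with the input signal."""

    e1: np.ndarray
    e2: np.ndarray
    e11: np.ndarray


@dataclass(frozen=True)
class DetectionMetrics:
    """Beat-detection counts and the derived sensitivity and precision."""

    tp: int
    fp: int
    fn: int

    @property
    def se(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("sensitivity undefined: TP + FN = 0")
        return self.tp / (self.tp + self.fn)

    @property
    def p(self) -> float:
        if self.tp + self.fp == 0:
            raise UndefinedMetricError("precision undefined: TP + FP = 0")
        return self.tp / (self.tp + self.fp)


def r_enhance(decomp: WaveletDecomposition) -> EnhancedSignal:
    """Compute e1, e2 and e11 from detail bands 3-5 of ``decomp``."""
    if decomp.levels < 5:
        raise InvalidArgumentError(
            f"decomposition depth {decomp.levels} < 5: bands d3..d5 unavailable")
    d3 = band_signal(decomp, 3)
    d4 = band_signal(decomp, 4)
    d5 = band_signal(decomp, 5)
    e1 = d3 + d4 + d5
    e2 = d4 * (2.0 * d3 + d5)
    return EnhancedSignal(e1=e1, e2=e2, e11=e1 * e2)


def combine_bands(d3, d4, d5) -> EnhancedSignal:
    """The four-operations algebra on already-aligned band signals."""
    d3, d4, d5 = (np.asarray(d, dtype=float) for d in (d3, d4, d5))
    e1 = d3 + d4 + d5
    e2 = d4 * (2.0 * d3 + d5)
    return EnhancedSignal(e1=e1, e2=e2, e11=e1 * e2)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strictly-rising, non-falling local maxima (edges count)."""
    if x.size == 0:
        return np.empty(0, dtype=np.int64)
    left = np.empty(x.size)
    right = np.empty(x.size)
    left[0], right[-1] = -np.inf, -np.inf
    left[1:] = x[:-1]
    right[:-1] = x[1:]
    return np.nonzero((x > left) & (x >= right))[0]


def detect_r_peaks(e11, window: int = DEFAULT_WINDOW, frac: float = DEFAULT_FRAC,
                   refractory: int = DEFAULT_REFRACTORY) -> np.ndarray:
    """Adaptive-threshold R-peak detection on the enhanced signal.

    Non-overlapping windows of ``window`` samples; within each, local maxima
    of positive value at or above ``frac`` times the window maximum are
    candidates.  Candidates closer than ``refractory`` samples are merged,
    keeping the larger.  Returns sorted 0-based indices.
    """
    x = np.asarray(e11, dtype=float)
    if window < 2:
        raise InvalidArgumentError(f"window must be >= 2, got {window}")
    if not 0 < frac < 1:
        raise InvalidArgumentError(f"frac must be in (0, 1), got {frac}")
    if x.size == 0:
        return np.empty(0, dtype=np.int64)
    # local maxima of the whole trace, so a window boundary cannot turn a
    # decaying slope into a spurious edge maximum
    maxima = _local_maxima(x)
    candidates = []
    for start in range(0, x.size, window):
        stop = start + window
        m = x[start:stop].max()
        if m <= 0:
            continue
        for i in maxima[(maxima >= start) & (maxima < stop)]:
            if x[i] > 0 and x[i] >= frac * m:
                candidates.append(int(i))
    if not candidates:
        return np.empty(0, dtype=np.int64)
    # refractory merge, keeping the larger of any pair closer than the gap
    kept: list[int] = []
    for idx in candidates:
        if kept and idx - kept[-1] < refractory:
            if x[idx] > x[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    return np.asarray(kept, dtype=np.int64)


def locate_fiducials(signal, r_indices, fs: float,
                     refine_radius: int = R_REFINE_RADIUS) -> FiducialSet:
    """Locate P, Q, R, S, T peaks around each detected R.

    The R index is refined to the local maximum of the *raw* signal within
    ``refine_radius`` samples of the enhanced-signal peak; Q and S are the
    minima of 100 ms windows before/after R; P is the maximum between
    R - 200 ms and Q; T the maximum in (S + 50 ms, S + 450 ms).  Windows are
    clipped at record edges and beats with an empty window are dropped.
    """
    if fs <= 0:
        raise InvalidArgumentError(f"fs must be positive, got {fs}")
    x = np.asarray(signal, dtype=float)
    n = x.size
    r_indices = np.asarray(r_indices, dtype=np.int64)
    if r_indices.size and (r_indices.min() < 0 or r_indices.max() >= n):
        raise InvalidArgumentError("r_indices must lie inside the signal")

    q_w = int(round(Q_WINDOW_S * fs))
    s_w = int(round(S_WINDOW_S * fs))
    p_w = int(round(P_WINDOW_S * fs))
    t_lo = int(round(T_START_S * fs))
    t_hi = int(round(T_END_S * fs))

    idx_rows, amp_rows, dropped = [], [], 0
    last_r = -1
    for r0 in r_indices:
        lo = max(0, r0 - refine_radius)
        hi = min(n, r0 + refine_radius + 1)
        r = lo + int(np.argmax(x[lo:hi]))
        if r == last_r:  # two enhanced-signal peaks refined onto one beat
            dropped += 1
            continue
        last_r = r

        q_lo, q_hi = max(0, r - q_w), r  # (R-100ms, R)
        s_lo, s_hi = r + 1, min(n, r + s_w + 1)  # (R, R+100ms]
        if q_hi <= q_lo or s_hi <= s_lo:
            dropped += 1
            continue
        q = q_lo + int(np.argmin(x[q_lo:q_hi]))
        s = s_lo + int(np.argmin(x[s_lo:s_hi]))

        p_lo, p_hi = max(0, r - p_w), q  # (R-200ms, Q)
        t_lo_i, t_hi_i = s + t_lo, min(n, s + t_hi + 1)
        if p_hi <= p_lo or t_hi_i <= t_lo_i or t_lo_i >= n:
            dropped += 1
            continue
        p = p_lo + int(np.argmax(x[p_lo:p_hi]))
        t = t_lo_i + int(np.argmax(x[t_lo_i:t_hi_i]))

        if not p < q < r < s < t:
            dropped += 1
            continue
        idx_rows.append([p, q, r, s, t])
        amp_rows.append(x[[p, q, r, s, t]])
    if dropped:
        logger.info("locate_fiducials: dropped %d beats with collapsed windows", dropped)
    if not idx_rows:
        return FiducialSet(idx=np.empty((0, 5), dtype=np.int64), amp=np.empty((0, 5)))
    return FiducialSet(idx=np.asarray(idx_rows), amp=np.asarray(amp_rows))


def detection_metrics(detected, truth, tol: int = DEFAULT_MATCH_TOL) -> DetectionMetrics:
    """Greedy one-to-one matching of detected vs true R indices within ±tol."""
    det = np.asarray(detected, dtype=np.int64)
    tru = np.asarray(truth, dtype=np.int64)
    if np.any(np.diff(det) < 0) or np.any(np.diff(tru) < 0):
        raise InvalidArgumentError("index lists must be sorted")
    i = j = tp = fp = fn = 0
    while i < det.size and j < tru.size:
        if abs(int(det[i]) - int(tru[j])) <= tol:
            tp += 1
            i += 1
            j += 1
        elif det[i] < tru[j] - tol:
            fp += 1
            i += 1
        else:
            fn += 1
            j += 1
    fp += det.size - i
    fn += tru.size - j
    return DetectionMetrics(tp=tp, fp=fp, fn=fn)
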