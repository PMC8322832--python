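"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class QrsnetError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(QrsnetError, ValueError):
    """An argument violates a documented precondition."""


@dataclass
class EcgSignal:
    """A sampled single-lead ECG trace in millivolts.

    Attributes
    ----------
    samples : ndarray of float, mV
    fs : float
        Sampling rate in Hz (MIT-BIH arrhythmia records use 360 Hz).
    lead : str
        Lead label, e.g. ``"MLII"`` or ``"V5"``.
    record_id : str
    """

    samples: np.ndarray
    fs: float
    lead: str = "MLII"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class AnnotationSet:
    """Beat annotations: 0-based sample index of each R peak plus class id.

    Class ids follow the convention 1=Nb, 2=Lbbb, 3=Rbbb, 4=Vpb, 5=Apb.
    """

    samples: np.ndarray  # 0-based R-peak indices, strictly increasing
    class_ids: np.ndarray  # integers in 1..5

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64)
        if self.samples.shape != self.class_ids.shape:
            raise InvalidArgumentError("samples and class_ids must have equal length")
        if self.samples.size > 1 and not np.all(np.diff(self.samples) > 0):
            raise InvalidArgumentError("annotation indices must be strictly increasing")

    def __len__(self) -> int:
        return self.samples.size


#: column order of a fiducial table
FIDUCIAL_WAVES = ("p", "q", "r", "s", "t")


@dataclass
class FiducialSet:
    """Per-beat P/Q/R/S/T peak sample indices and the signal amplitude at each.

    ``idx`` is an (n_beats, 5) integer array ordered P,Q,R,S,T; ``amp`` the
    matching amplitudes in mV.  Invariant per beat: p < q < r < s < t.
    """

    idx: np.ndarray
    amp: np.ndarray

    def __post_init__(self) -> None:
        self.idx = np.asarray(self.idx, dtype=np.int64).reshape(-1, 5)
        self.amp = np.asarray(self.amp, dtype=float).reshape(-1, 5)
        if self.idx.shape != self.amp.shape:
            raise InvalidArgumentError("idx and amp must have the same shape")

    def __len__(self) -> int:
        return self.idx.shape[0]

    @property
    def r_indices(self) -> np.ndarray:
        return self.idx[:, 2]

    def check_ordering(self) -> bool:
        """True when every beat satisfies p < q < r < s < t."""
        return bool(np.all(np.diff(self.idx, axis=1) > 0))
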