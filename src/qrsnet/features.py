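"""Beat segmentation, the 16-feature beat descriptor, and dataset assembly.

Each beat is described by the vector

    F = [PQ, PR, PS, PT, QR, QS, QT, RS, RT, ST,
         ampP, ampQ, ampR, ampS, ampT, H]

where the first ten entries are absolute time differences (seconds) between
the peak positions of the named waves, the five amplitudes are the signal
values (mV) at those peaks, and H is the instantaneous heart rate in
beats/min computed from the preceding R-to-R interval (the following
interval for the first beat of a record, where no preceding one exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import FiducialSet, InvalidArgumentError

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "PQ", "PR", "PS", "PT", "QR", "QS", "QT", "RS", "RT", "ST",
    "ampP", "ampQ", "ampR", "ampS", "ampT", "H",
)

_PAIRS = ((0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))

BEAT_PRE = 99  # samples kept before R
BEAT_POST = 200  # samples kept after R


class IncompleteBeatError(ValueError):
    """A beat is missing one of its five fiducials."""


class InsufficientDataError(ValueError):
    """A class supplies fewer beats than requested."""


@dataclass
class FeatureTable:
    """n x 16 feature matrix with per-row class labels.

    ``norm_params`` holds the per-feature (min, max) learned on training
    rows once :func:`normalize` has been applied.
    """

    rows: np.ndarray
    labels: np.ndarray
    norm_params: np.ndarray | None = None  # (16, 2): column 0 = min, 1 = max

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float).reshape(-1, len(FEATURE_NAMES))
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.rows.shape[0] != self.labels.shape[0]:
            raise InvalidArgumentError("rows and labels must have equal length")

    def __len__(self) -> int:
        return self.rows.shape[0]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def segment_beats(signal, r_indices, pre: int = BEAT_PRE, post: int = BEAT_POST):
    """Cut a fixed window around each R peak.

    Returns ``(segments, kept)`` where ``segments`` is (k, pre+post+1) and
    ``kept`` indexes the surviving entries of ``r_indices``; edge-clipped
    beats are dropped and logged.
    """
    x = np.asarray(signal, dtype=float)
    r_indices = np.asarray(r_indices, dtype=np.int64)
    keep = (r_indices >= pre) & (r_indices + post < x.size)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("segment_beats: dropped %d edge-clipped beats", dropped)
    kept = np.nonzero(keep)[0]
    segments = np.stack([x[r - pre : r + post + 1] for r in r_indices[kept]]) \
        if kept.size else np.empty((0, pre + post + 1))
    return segments, kept


def beat_features(idx, amp, fs: float, rr_neighbor: float) -> np.ndarray:
    """The 16-entry descriptor for one beat.

    ``idx``/``amp`` are length-5 arrays ordered P,Q,R,S,T.
    """
    if fs <= 0 or rr_neighbor <= 0:
        raise InvalidArgumentError("fs and rr_neighbor must be positive")
    idx = np.asarray(idx)
    amp = np.asarray(amp, dtype=float)
    if idx.shape != (5,) or amp.shape != (5,):
        raise IncompleteBeatError(f"expected 5 fiducials, got idx {idx.shape}, amp {amp.shape}")
    if np.any(idx < 0) or not np.all(np.isfinite(amp)):
        raise IncompleteBeatError("beat has a missing or invalid fiducial")
    diffs = [abs(int(idx[b]) - int(idx[a])) / fs for a, b in _PAIRS]
    return np.asarray(diffs + list(amp) + [60.0 / rr_neighbor])


def rr_neighbors(r_indices, fs: float) -> np.ndarray:
    """Preceding R-to-R interval per beat, seconds; first beat uses the next."""
    r = np.asarray(r_indices, dtype=np.int64)
    if r.size < 2:
        raise InvalidArgumentError("need at least two beats for an RR interval")
    rr = np.diff(r) / fs
    return np.concatenate([[rr[0]], rr])


def extract_features(fiducials: FiducialSet, fs: float, labels) -> FeatureTable:
    """Descriptor rows for every beat of a record, in record order."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(fiducials) != labels.size:
        raise InvalidArgumentError("one label per beat required")
    rr = rr_neighbors(fiducials.r_indices, fs)
    rows = [beat_features(fiducials.idx[k], fiducials.amp[k], fs, rr[k])
            for k in range(len(fiducials))]
    return FeatureTable(rows=np.asarray(rows), labels=labels)


def build_dataset(per_class_rows: dict, n_per_class: int = 30):
    """First-``n_per_class``-beats split: first half train, second half test.

    ``per_class_rows`` maps class id -> feature rows in record order.  The
    first ``n_per_class`` beats of each class are taken; the first half of
    each class's selection goes to the training table, the second half to
    the test table.  Classes are assembled in ascending id order, so the
    result does not depend on dict insertion order.
    """
    if n_per_class < 2:
        raise InvalidArgumentError("n_per_class must be >= 2")
    class_ids = sorted(per_class_rows)
    if len(class_ids) < 2:
        raise InsufficientDataError("need at least two classes")
    half = n_per_class // 2
    train_rows, train_labels, test_rows, test_labels = [], [], [], []
    for cid in class_ids:
        rows = np.asarray(per_class_rows[cid], dtype=float)
        if rows.shape[0] < n_per_class:
            raise InsufficientDataError(
                f"class {cid} supplies {rows.shape[0]} beats, needs {n_per_class}")
        sel = rows[:n_per_class]
        train_rows.append(sel[:half])
        test_rows.append(sel[half:])
        train_labels.extend([cid] * half)
        test_labels.extend([cid] * (n_per_class - half))
    train = FeatureTable(rows=np.vstack(train_rows), labels=np.asarray(train_labels))
    test = FeatureTable(rows=np.vstack(test_rows), labels=np.asarray(test_labels))
    return train, test


def group_by_class(table: FeatureTable) -> dict:
    """Split a record-ordered table into per-class row arrays (order kept)."""
    return {int(cid): table.rows[table.labels == cid] for cid in np.unique(table.labels)}


def normalize(train: FeatureTable, test: FeatureTable | None = None):
    """Affine map per feature sending the training min/max to [-1, +1].

    The same map is applied to the test rows, which are then clipped to
    [-1, 1] (the network declares fixed input ranges).  Constant features
    map to 0.  Returns ``(train', test', norm_params)``; ``test'`` is None
    when no test table is given.
    """
    if len(train) == 0:
        raise InvalidArgumentError("training table must be non-empty")
    lo = train.rows.min(axis=0)
    hi = train.rows.max(axis=0)
    params = np.column_stack([lo, hi])

    def apply(rows, clip):
        span = hi - lo
        out = np.zeros_like(rows)
        nz = span > 0
        out[:, nz] = 2.0 * (rows[:, nz] - lo[nz]) / span[nz] - 1.0
        if clip:
            out = np.clip(out, -1.0, 1.0)
        return out

    train_n = FeatureTable(rows=apply(train.rows, clip=False), labels=train.labels,
                           norm_params=params)
    test_n = None
    if test is not None:
        test_n = FeatureTable(rows=apply(test.rows, clip=True), labels=test.labels,
                              norm_params=params)
    return train_n, test_n, params


def denormalize(rows, norm_params) -> np.ndarray:
    """Invert :func:`normalize` (constant features return their min)."""
    lo, hi = norm_params[:, 0], norm_params[:, 1]
    span = hi - lo
    out = np.asarray(rows, dtype=float) * 0 + lo
    nz = span > 0
    out[:, nz] = (np.asarray(rows, dtype=float)[:, nz] + 1.0) / 2.0 * span[nz] + lo[nz]
    return out
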