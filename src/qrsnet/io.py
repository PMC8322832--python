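"""Record and feature-table input/output.

Reads WFDB records and beat annotations (via :mod:`qrsnet.wfdb_io`), maps
MIT beat symbols to the five class ids used throughout (1=Nb, 2=Lbbb,
3=Rbbb, 4=Vpb, 5=Apb), and round-trips CSV feature tables and plain CSV
signal dumps.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from . import wfdb_io
from .features import FEATURE_NAMES, FeatureTable
from .types import AnnotationSet, EcgSignal, InvalidArgumentError
from .wfdb_io import LeadNotFoundError

logger = logging.getLogger(__name__)

#: MIT beat symbol -> class id (all other symbols are dropped)
SYMBOL_CLASS_MAP = {"N": 1, "L": 2, "R": 3, "V": 4, "A": 5}


class SchemaError(ValueError):
    """A CSV table does not match the expected column schema."""


def read_record(path: str, lead: str = "MLII") -> EcgSignal:
    """Read one channel of a WFDB record in physical units (mV).

    ``path`` is the ``.hea`` file or the record path without extension.
    """
    hea = path if path.endswith(".hea") else path + ".hea"
    header, samples = wfdb_io.read_signals(hea)
    leads = [s.description for s in header.signals]
    if lead not in leads:
        raise LeadNotFoundError(f"lead {lead!r} not in record {header.record_name}; available: {leads}")
    col = leads.index(lead)
    return EcgSignal(samples=samples[:, col], fs=header.fs, lead=lead, record_id=header.record_name)


def write_record(directory: str, signal: EcgSignal, annotations: AnnotationSet | None = None) -> str:
    """Write a signal (and optionally its beat annotations) in WFDB layout."""
    hea = wfdb_io.write_record(directory, signal.record_id or "rec", signal.samples, signal.fs, [signal.lead])
    if annotations is not None:
        inv = {v: k for k, v in SYMBOL_CLASS_MAP.items()}
        symbols = [inv[int(c)] for c in annotations.class_ids]
        wfdb_io.write_annotations(os.path.join(directory, f"{signal.record_id or 'rec'}.atr"),
                                  annotations.samples, symbols)
    return hea


def read_annotations(path: str) -> AnnotationSet:
    """Read an ``.atr`` file, keeping only the five mapped beat classes."""
    samples, symbols = wfdb_io.read_annotations(path)
    class_ids = map_beat_symbols(symbols)
    keep = np.fromiter((s in SYMBOL_CLASS_MAP for s in symbols), dtype=bool, count=len(symbols))
    return AnnotationSet(samples=samples[keep], class_ids=np.asarray(class_ids, dtype=np.int64))


def map_beat_symbols(symbols) -> list:
    """Map MIT beat symbols to class ids; unknown symbols are dropped.

    N->1, L->2, R->3, V->4, A->5.  The number of dropped symbols is logged.
    """
    out = [SYMBOL_CLASS_MAP[s] for s in symbols if s in SYMBOL_CLASS_MAP]
    dropped = len(list(symbols)) - len(out)
    if dropped:
        logger.info("map_beat_symbols: dropped %d unmapped symbols", dropped)
    return out


def write_signal_csv(path: str, signal: EcgSignal) -> None:
    """Plain CSV dump: header ``sample_index,value`` (mV)."""
    df = pd.DataFrame({"sample_index": np.arange(len(signal)), "value": signal.samples})
    df.to_csv(path, index=False, float_format="%.10g")


def read_signal_csv(path: str, fs: float = 360.0, lead: str = "MLII", record_id: str = "") -> EcgSignal:
    df = pd.read_csv(path)
    if list(df.columns) != ["sample_index", "value"]:
        raise SchemaError(f"expected columns ['sample_index', 'value'], got {list(df.columns)}")
    return EcgSignal(samples=df["value"].to_numpy(), fs=fs, lead=lead, record_id=record_id)


def write_feature_table(path: str, table: FeatureTable) -> None:
    """CSV with the 16 feature columns plus ``class_id``; 10 significant digits."""
    df = pd.DataFrame(table.rows, columns=list(FEATURE_NAMES))
    df["class_id"] = table.labels
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str) -> FeatureTable:
    df = pd.read_csv(path)
    expected = list(FEATURE_NAMES) + ["class_id"]
    if list(df.columns) != expected:
        raise SchemaError(f"expected columns {expected}, got {list(df.columns)}")
    return FeatureTable(
        rows=df[list(FEATURE_NAMES)].to_numpy(dtype=float),
        labels=df["class_id"].to_numpy(dtype=np.int64),
    )
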