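"""Minimal WFDB record and annotation support.

Implements the subset of the WFDB conventions the pipeline needs: text
``.hea`` headers, signal files in format 16 (little-endian int16, written
and read) and format 212 (12-bit packed pairs, read only — the encoding the
MIT-BIH arrhythmia database uses), and the MIT two-byte ``.atr`` annotation
stream for beat labels.

Values are converted to physical units as ``(adc - baseline) / gain`` mV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .types import InvalidArgumentError


class WfdbParseError(Exception):
    """Malformed header, signal, or annotation file."""


class LeadNotFoundError(KeyError):
    """Requested lead absent from the record header."""


# MIT annotation codes <-> display symbols (beat subset plus common extras)
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f", 39: "(",
    40: ")", 41: "r",
}
SYMBOL_TO_CODE = {s: c for c, s in CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    description: str  # lead name


@dataclass
class Header:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list


def read_header(path: str) -> Header:
    """Parse a ``.hea`` file (comment lines starting with ``#`` ignored)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise WfdbParseError(f"empty header: {path}")
    head = lines[0].split()
    if len(head) < 3:
        raise WfdbParseError(f"bad record line in {path}: {lines[0]!r}")
    record_name = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
        n_samples = int(head[3]) if len(head) > 3 else 0
    except ValueError as exc:
        raise WfdbParseError(f"bad record line in {path}: {lines[0]!r}") from exc
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise WfdbParseError(f"bad signal line in {path}: {ln!r}")
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        if baseline is None:
            baseline = int(tok[4]) if len(tok) > 4 else 0  # adc zero
        description = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(SignalSpec(tok[0], fmt, gain, baseline, description))
    return Header(record_name, n_sig, fs, n_samples, signals)


def _read_dat_16(path: str, n_sig: int) -> np.ndarray:
    raw = np.fromfile(path, dtype="<i2")
    n = raw.size // n_sig
    return raw[: n * n_sig].reshape(n, n_sig)


def _read_dat_212(path: str, n_sig: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    raw = raw[: (raw.size // 3) * 3].reshape(-1, 3)
    s0 = (raw[:, 0].astype(np.int32) | ((raw[:, 1].astype(np.int32) & 0x0F) << 8))
    s1 = (raw[:, 2].astype(np.int32) | ((raw[:, 1].astype(np.int32) & 0xF0) << 4))
    # sign-extend from 12 bits
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    flat = np.empty(s0.size * 2, dtype=np.int32)
    flat[0::2], flat[1::2] = s0, s1
    n = flat.size // n_sig
    return flat[: n * n_sig].reshape(n, n_sig)


def read_signals(header_path: str) -> tuple[Header, np.ndarray]:
    """Read all channels of a record in physical units (mV).

    Returns ``(header, samples)`` with ``samples`` shaped (n, n_sig).
    """
    header = read_header(header_path)
    base = os.path.dirname(header_path)
    by_file: dict[str, list[int]] = {}
    for i, spec in enumerate(header.signals):
        by_file.setdefault(spec.file_name, []).append(i)
    out = [None] * header.n_sig
    for fname, idxs in by_file.items():
        fmt = header.signals[idxs[0]].fmt
        path = os.path.join(base, fname)
        if fmt == 16:
            adc = _read_dat_16(path, len(idxs))
        elif fmt == 212:
            adc = _read_dat_212(path, len(idxs))
        else:
            raise WfdbParseError(f"unsupported signal format {fmt} in {path}")
        for col, i in enumerate(idxs):
            spec = header.signals[i]
            out[i] = (adc[:, col].astype(float) - spec.baseline) / spec.gain
    n = min(o.size for o in out)
    if header.n_samples:
        n = min(n, header.n_samples)
    return header, np.column_stack([o[:n] for o in out])


def write_record(
    directory: str,
    record_name: str,
    samples: np.ndarray,
    fs: float,
    leads,
    gain: float = 200.0,
) -> str:
    """Write a record as ``.hea`` + format-16 ``.dat``; returns the .hea path."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < samples.shape[1]:  # accept (n_sig, n) layouts
        samples = samples.T
    n, n_sig = samples.shape
    if isinstance(leads, str):
        leads = [leads]
    if len(leads) != n_sig:
        raise InvalidArgumentError("one lead name per channel required")
    adc = np.clip(np.round(samples * gain), -32768, 32767).astype("<i2")
    os.makedirs(directory, exist_ok=True)
    dat_name = f"{record_name}.dat"
    adc.reshape(-1).tofile(os.path.join(directory, dat_name))
    hea_path = os.path.join(directory, f"{record_name}.hea")
    with open(hea_path, "w") as fh:
        fh.write(f"{record_name} {n_sig} {fs:g} {n}\n")
        for j, lead in enumerate(leads):
            checksum = int(adc[:, j].astype(np.int64).sum() % 65536)
            fh.write(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {int(adc[0, j])} {checksum} 0 {lead}\n")
    return hea_path


def read_annotations(path: str) -> tuple[np.ndarray, list]:
    """Read an MIT-format annotation file; returns (sample_indices, symbols)."""
    raw = np.fromfile(path, dtype="<u2")
    samples, symbols = [], []
    t = 0
    i = 0
    pending_skip = 0
    while i < raw.size:
        word = int(raw[i])
        code, delta = word >> 10, word & 0x3FF
        i += 1
        if word == 0:
            break
        if code == _SKIP:
            if i + 1 >= raw.size:
                raise WfdbParseError(f"truncated SKIP in {path}")
            pending_skip = (int(raw[i]) << 16) | int(raw[i + 1])
            if pending_skip >= 1 << 31:
                pending_skip -= 1 << 32
            i += 2
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += (delta + 1) // 2
        else:
            t += delta + pending_skip
            pending_skip = 0
            samples.append(t)
            symbols.append(CODE_TO_SYMBOL.get(code, "?"))
    return np.asarray(samples, dtype=np.int64), symbols


def write_annotations(path: str, samples, symbols) -> None:
    """Write beat annotations in the MIT two-byte stream format."""
    samples = np.asarray(samples, dtype=np.int64)
    if samples.size != len(symbols):
        raise InvalidArgumentError("samples and symbols must have equal length")
    if samples.size > 1 and not np.all(np.diff(samples) > 0):
        raise InvalidArgumentError("annotation samples must be strictly increasing")
    words = []
    prev = 0
    for s, sym in zip(samples, symbols):
        code = SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise InvalidArgumentError(f"no MIT code for symbol {sym!r}")
        delta = int(s - prev)
        prev = int(s)
        if delta > 1023:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
    words.append(0)
    np.asarray(words, dtype="<u2").tofile(path)
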