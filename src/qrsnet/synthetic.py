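"""Synthetic ECG generator with analytic fiducial ground truth.

Beats are sums of five Gaussian bumps (P, Q, R, S, T), one beat per RR
interval, so every wave's extremum is known exactly: it falls at the sample
nearest the wave's center.  Five presets emulate the morphologies the
pipeline must distinguish:

* ``Nb``   (1) - normal beat,
* ``Lbbb`` (2) - left bundle branch block: widened QRS, broad dominant R,
* ``Rbbb`` (3) - right bundle branch block: widened QRS, deep S,
* ``Vpb``  (4) - ventricular premature beat: wide large QRS, absent P,
  shortened preceding RR,
* ``Apb``  (5) - atrial premature beat: small P, shortened preceding RR.

Noise is additive: a sub-1 Hz baseline-wander sinusoid, Gaussian white
noise, and an optional powerline sinusoid; all randomness flows through one
explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AnnotationSet, EcgSignal, FiducialSet, InvalidArgumentError

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: seconds from beat onset to the R center; every wave offset is relative to R
R_OFFSET_S = 0.30

#: fraction by which a premature beat (Vpb/Apb) shortens the preceding RR
PREMATURE_RR_FRACTION = 0.7

CLASS_NAMES = {1: "Nb", 2: "Lbbb", 3: "Rbbb", 4: "Vpb", 5: "Apb"}


@dataclass(frozen=True)
class BeatPreset:
    """One beat morphology: per-wave (amplitude mV, center s rel. R, width s)."""

    class_id: int
    wave_params: dict  # name -> (amp, center, width)
    rr_interval: float  # seconds

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_NAMES:
            raise InvalidArgumentError(f"class_id must be 1..5, got {self.class_id}")
        if self.rr_interval <= 0:
            raise InvalidArgumentError("rr_interval must be positive")
        missing = set(WAVE_NAMES) - set(self.wave_params)
        if missing:
            raise InvalidArgumentError(f"missing wave parameters: {sorted(missing)}")
        for name, (_, _, width) in self.wave_params.items():
            if width <= 0:
                raise InvalidArgumentError(f"wave {name} width must be positive")
        centers = [self.wave_params[w][1] for w in WAVE_NAMES]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise InvalidArgumentError("wave centers must be ordered P < Q < R < S < T")
        amp_r = self.wave_params["R"][0]
        amp_q = abs(self.wave_params["Q"][0])
        amp_s = abs(self.wave_params["S"][0])
        if (amp_r, amp_q, amp_s) != (0.0, 0.0, 0.0) and not (amp_r > amp_q and amp_r > amp_s):
            raise InvalidArgumentError("R amplitude must dominate |Q| and |S|")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise model: baseline sinusoid + white noise + powerline."""

    baseline_amp: float = 0.1  # mV
    baseline_freq: float = 0.3  # Hz, must stay below 1 Hz (drift band)
    white_sd: float = 0.02  # mV
    powerline_amp: float = 0.0  # mV
    powerline_freq: float = 50.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.white_sd, self.powerline_amp) < 0:
            raise InvalidArgumentError("noise amplitudes must be non-negative")
        if not 0 <= self.baseline_freq < 1:
            raise InvalidArgumentError("baseline_freq must lie in [0, 1) Hz")
        if self.powerline_freq not in (50.0, 60.0):
            raise InvalidArgumentError("powerline_freq must be 50 or 60 Hz")


def default_presets() -> dict:
    """The five documented beat-morphology presets, keyed by class id."""
    return {
        1: BeatPreset(1, {
            "P": (0.15, -0.16, 0.025),
            "Q": (-0.10, -0.040, 0.012),
            "R": (1.00, 0.0, 0.018),
            "S": (-0.20, 0.040, 0.015),
            "T": (0.30, 0.185, 0.050),
        }, rr_interval=0.90),
        2: BeatPreset(2, {
            "P": (0.12, -0.17, 0.025),
            "Q": (-0.05, -0.060, 0.020),
            "R": (1.10, 0.0, 0.035),
            "S": (-0.45, 0.070, 0.030),
            "T": (0.35, 0.195, 0.055),
        }, rr_interval=0.92),
        3: BeatPreset(3, {
            "P": (0.14, -0.16, 0.025),
            "Q": (-0.15, -0.050, 0.015),
            "R": (0.90, 0.0, 0.030),
            "S": (-0.55, 0.060, 0.025),
            "T": (0.25, 0.185, 0.050),
        }, rr_interval=0.78),
        4: BeatPreset(4, {
            "P": (0.0, -0.18, 0.030),
            "Q": (-0.20, -0.070, 0.025),
            "R": (1.30, 0.0, 0.045),
            "S": (-0.50, 0.080, 0.035),
            "T": (0.20, 0.195, 0.060),
        }, rr_interval=0.82),
        5: BeatPreset(5, {
            "P": (0.08, -0.14, 0.020),
            "Q": (-0.10, -0.040, 0.012),
            "R": (0.95, 0.0, 0.018),
            "S": (-0.18, 0.040, 0.015),
            "T": (0.28, 0.180, 0.048),
        }, rr_interval=0.74),
    }


def synth_beat(preset: BeatPreset, fs: float, rr_interval: float | None = None):
    """Render one beat; returns ``(samples, truth_fiducials)``.

    ``samples`` has length ``round(rr * fs)``; ``truth_fiducials`` maps wave
    name to the 0-based sample index of the wave's extremum (its analytic
    center, clipped into the beat).
    """
    if fs <= 0:
        raise InvalidArgumentError(f"fs must be positive, got {fs}")
    rr = preset.rr_interval if rr_interval is None else rr_interval
    if rr <= 0:
        raise InvalidArgumentError("rr_interval must be positive")
    n = int(round(rr * fs))
    t = np.arange(n) / fs
    samples = np.zeros(n)
    centers = {}
    for name in WAVE_NAMES:
        amp, center, width = preset.wave_params[name]
        c = R_OFFSET_S + center
        samples += amp * np.exp(-((t - c) ** 2) / (2.0 * width**2))
        centers[name] = (int(np.clip(round(c * fs), 0, n - 1)), amp, width)
    # overlapping waves shift the summed trace's extremum by a sample or
    # two, so the stored truth is the rendered extremum near each center
    # (the analytic center itself for a zero-amplitude wave)
    truth = {}
    for name, (c_idx, amp, width) in centers.items():
        if amp == 0.0:
            truth[name] = c_idx
            continue
        radius = max(1, int(round(width * fs)))
        lo, hi = max(0, c_idx - radius), min(n, c_idx + radius + 1)
        seg = samples[lo:hi]
        truth[name] = lo + int(np.argmax(seg) if amp > 0 else np.argmin(seg))
    return samples, truth


def synth_record(
    class_sequence,
    presets: dict | None = None,
    fs: float = 360.0,
    noise: NoiseConfig | None = None,
    premature_rr_fraction: float = PREMATURE_RR_FRACTION,
    record_id: str = "synth",
):
    """Concatenate beats into one record and add noise.

    A premature beat (class 4 or 5) shortens the *preceding* beat's RR
    interval by ``premature_rr_fraction`` so that heart-rate features
    discriminate.  Returns ``(EcgSignal, AnnotationSet, FiducialSet)`` where
    the fiducials are the noise-free ground truth (indices and clean-trace
    amplitudes).
    """
    class_sequence = list(class_sequence)
    if not class_sequence:
        raise InvalidArgumentError("class_sequence must be non-empty")
    if presets is None:
        presets = default_presets()
    for cid in class_sequence:
        if cid not in presets:
            raise InvalidArgumentError(f"unknown class_id {cid!r}: no preset")
    if noise is None:
        noise = NoiseConfig(baseline_amp=0.0, white_sd=0.0)

    # effective RR per beat: shortened when the NEXT beat is premature
    rrs = []
    for k, cid in enumerate(class_sequence):
        rr = presets[cid].rr_interval
        if k + 1 < len(class_sequence) and class_sequence[k + 1] in (4, 5):
            rr *= premature_rr_fraction
        rrs.append(rr)

    chunks, ann_idx, ann_cls, fid_idx = [], [], [], []
    start = 0
    for cid, rr in zip(class_sequence, rrs):
        samples, truth = synth_beat(presets[cid], fs, rr_interval=rr)
        chunks.append(samples)
        ann_idx.append(start + truth["R"])
        ann_cls.append(cid)
        fid_idx.append([start + truth[w] for w in WAVE_NAMES])
        start += samples.size
    clean = np.concatenate(chunks)

    fid_idx = np.asarray(fid_idx, dtype=np.int64)
    fiducials = FiducialSet(idx=fid_idx, amp=clean[fid_idx])

    rng = np.random.default_rng(noise.seed)
    t = np.arange(clean.size) / fs
    noisy = clean + noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t)
    if noise.white_sd > 0:
        noisy = noisy + rng.normal(0.0, noise.white_sd, size=clean.size)
    if noise.powerline_amp > 0:
        noisy = noisy + noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_freq * t)

    signal = EcgSignal(samples=noisy, fs=fs, lead="MLII", record_id=record_id)
    annotations = AnnotationSet(samples=np.asarray(ann_idx), class_ids=np.asarray(ann_cls))
    return signal, annotations, fiducials


def interleaved_sequence(n_per_class: int, class_ids=(2, 4, 1, 5, 3)) -> list:
    """Round-robin class sequence, ``n_per_class`` beats of each class.

    The default cycle places each premature class (Vpb, Apb) after a
    long-RR conducted beat, the way ectopy interrupts an otherwise regular
    rhythm; the compensatory shortening then still leaves a physiologic gap.
    """
    return [cid for _ in range(n_per_class) for cid in class_ids]
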