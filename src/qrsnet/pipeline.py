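"""End-to-end orchestration: simulate/load -> denoise -> detect -> features
-> optional PCA -> train -> evaluate.

A master seed is split into per-stage sub-seeds through
``numpy.random.SeedSequence(seed).spawn``, so any stage can be re-run in
isolation with the same stream it saw inside the full pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import bpnn, pso
from . import features as ft
from . import fiducial as fd
from . import pca as pc
from .denoise import DEFAULT_BASIS, decompose, denoise as denoise_signal
from .synthetic import NoiseConfig, default_presets, interleaved_sequence, synth_record
from .types import AnnotationSet, EcgSignal, InvalidArgumentError

logger = logging.getLogger(__name__)

REPORT_VERSION = 1

#: extra beats simulated per class so that a rare missed detection cannot
#: starve the first-30-beats selection
SIM_MARGIN = 2


@dataclass
class PipelineConfig:
    """Everything one run needs; every stochastic stage draws a sub-seed."""

    seed: int = 0
    model: str = "pso-bpnn"  # "bpnn" | "pso-bpnn"
    n_per_class: int = 30
    pca_contrib: float | None = None  # off | 0.85 | 0.99
    basis: str = DEFAULT_BASIS
    window: int = fd.DEFAULT_WINDOW
    frac: float = fd.DEFAULT_FRAC
    hidden: int = 5
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    swarm: pso.SwarmConfig = field(default_factory=pso.SwarmConfig)
    train: bpnn.TrainConfig = field(default_factory=bpnn.TrainConfig)

    def __post_init__(self) -> None:
        if self.model not in ("bpnn", "pso-bpnn"):
            raise InvalidArgumentError(f"model must be 'bpnn' or 'pso-bpnn', got {self.model!r}")
        if self.pca_contrib is not None and not 0 < self.pca_contrib < 1:
            raise InvalidArgumentError("pca_contrib must be in (0, 1) or None")


def stage_seeds(master: int, n: int = 4) -> list:
    """Derive ``n`` independent sub-seeds (< 2**31) from the master seed."""
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(master).spawn(n)]


def match_labels(fiducials, annotations: AnnotationSet, tol: int = fd.DEFAULT_MATCH_TOL):
    """Assign each located beat the class of the nearest annotation within ±tol.

    Returns (kept beat positions, labels); unmatched beats are dropped.
    """
    keep, labels = [], []
    ann = annotations.samples
    for k, r in enumerate(fiducials.r_indices):
        j = int(np.argmin(np.abs(ann - r)))
        if abs(int(ann[j]) - int(r)) <= tol:
            keep.append(k)
            labels.append(int(annotations.class_ids[j]))
    return np.asarray(keep, dtype=np.int64), np.asarray(labels, dtype=np.int64)


def detect_beats(signal: EcgSignal, basis: str, window: int, frac: float):
    """Denoise, enhance, and locate all five fiducials for every beat."""
    filtered = denoise_signal(signal.samples, basis=basis)
    decomp = decompose(filtered, basis=basis)
    enhanced = fd.r_enhance(decomp)
    r_peaks = fd.detect_r_peaks(enhanced.e11, window=window, frac=frac)
    fiducials = fd.locate_fiducials(filtered, r_peaks, signal.fs)
    return filtered, fiducials


def evaluate(params: bpnn.NetworkParams, X, labels) -> dict:
    """Accuracy, per-class accuracy, and the 5x5 confusion matrix."""
    pred = bpnn.predict_classes(params, X)
    labels = np.asarray(labels, dtype=np.int64)
    acc = bpnn.accuracy(pred, labels)
    confusion = np.zeros((bpnn.N_CLASSES, bpnn.N_CLASSES), dtype=int)
    for a, p in zip(labels, pred):
        confusion[a - 1, p - 1] += 1
    per_class = {}
    for c in range(1, bpnn.N_CLASSES + 1):
        n_c = int(confusion[c - 1].sum())
        per_class[c] = 100.0 * confusion[c - 1, c - 1] / n_c if n_c else float("nan")
    return {"accuracy": acc, "per_class_accuracy": per_class,
            "confusion": confusion.tolist(), "predicted": pred}


def run_pipeline(config: PipelineConfig) -> dict:
    """Full run on a synthetic record; returns the report dictionary."""
    t0 = time.time()
    noise_seed, net_seed, pso_seed, _ = stage_seeds(config.seed)

    # --- simulate ---------------------------------------------------------
    sequence = interleaved_sequence(config.n_per_class + SIM_MARGIN)
    noise = dataclasses.replace(config.noise, seed=noise_seed)
    signal, annotations, _truth = synth_record(sequence, default_presets(),
                                               fs=360.0, noise=noise)
    logger.info("simulate: %d beats, %d samples", len(annotations), len(signal))

    # --- denoise + detect -------------------------------------------------
    _, fiducials = detect_beats(signal, config.basis, config.window, config.frac)
    det = fd.detection_metrics(fiducials.r_indices, annotations.samples)
    logger.info("detect: TP=%d FP=%d FN=%d Se=%.4f P=%.4f",
                det.tp, det.fp, det.fn, det.se, det.p)

    # --- features ---------------------------------------------------------
    keep, labels = match_labels(fiducials, annotations)
    from .types import FiducialSet

    matched = FiducialSet(idx=fiducials.idx[keep], amp=fiducials.amp[keep])
    table = ft.extract_features(matched, signal.fs, labels)
    train_t, test_t = ft.build_dataset(ft.group_by_class(table), config.n_per_class)
    train_n, test_n, _ = ft.normalize(train_t, test_t)

    # --- optional PCA -----------------------------------------------------
    pca_dim = None
    X_train, X_test = train_n.rows, test_n.rows
    if config.pca_contrib is not None:
        model = pc.fit_pca(X_train)
        pca_dim = pc.select_dim(model, config.pca_contrib)
        X_train = pc.transform(model, X_train, pca_dim)
        X_test = pc.transform(model, X_test, pca_dim)
    input_dim = X_train.shape[1]

    # --- train ------------------------------------------------------------
    layer_sizes = (input_dim, config.hidden, 1)
    T_train = train_n.labels.astype(float).reshape(-1, 1)
    train_cfg = dataclasses.replace(config.train, seed=net_seed)
    if config.model == "bpnn":
        params0 = bpnn.init_network(layer_sizes, seed=net_seed)
        params, history = bpnn.train(params0, X_train, T_train, train_cfg)
    else:
        swarm_cfg = dataclasses.replace(config.swarm, seed=pso_seed)
        params, info = pso.train_pso_bpnn(X_train, T_train, swarm_cfg, train_cfg,
                                          layer_sizes=layer_sizes)
        history = info["train_history"]

    # --- evaluate ---------------------------------------------------------
    ev = evaluate(params, X_test, test_n.labels)
    logger.info("pipeline finished in %.2f s", time.time() - t0)
    report = {
        "report_version": REPORT_VERSION,
        "seed": config.seed,
        "model": config.model,
        "n_train": int(len(train_n)),
        "n_test": int(len(test_n)),
        "detection": {"tp": det.tp, "fp": det.fp, "fn": det.fn,
                      "se": det.se, "p": det.p},
        "pca_contrib": config.pca_contrib,
        "pca_dim": pca_dim,
        "input_dim": int(input_dim),
        "accuracy": ev["accuracy"],
        "per_class_accuracy": {str(k): v for k, v in ev["per_class_accuracy"].items()},
        "confusion": ev["confusion"],
        "train_final_mse": float(history[-1][0]),
        "epochs_run": len(history) - 1,
        "config": {
            "basis": config.basis, "window": config.window, "frac": config.frac,
            "n_per_class": config.n_per_class, "hidden": config.hidden,
            "noise": dataclasses.asdict(noise),
        },
    }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
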