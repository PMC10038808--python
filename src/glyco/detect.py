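"""Sequence classifiers for unannounced meal / physical-activity
detection.

Windows of 24 past samples (2 h) of the selected features predict the
four-class label one sample backward: the window ending at sample k is
labeled with the event class at k, so an event is recognized after its
effect has appeared in the data.  Four recurrent architectures are
provided: (a) masked LSTM, (b) 1-D convolution + LSTM, (c) 2-D
ConvLSTM on the degenerate 1x1 spatial grid, (d) 1-D convolution +
bidirectional LSTM.  Training follows a chronological 87.5/12.5
development/test split, stratified k-fold cross-validation inside the
development split, inverse-class-size sample weights, Adam with a
reduced learning rate for convolutional models, and multiple seeded
restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)
from sklearn.model_selection import StratifiedKFold

from . import nn
from .features import FeatureTable

log = logging.getLogger("glyco")

WINDOW = 24
ARCHITECTURES = ("lstm", "conv1d_lstm", "convlstm2d", "conv1d_bilstm")


@dataclass
class SequenceBatch:
    """Windows x lags x features tensors with one-hot targets."""

    inputs: np.ndarray         # (n, 24, F)
    targets: np.ndarray        # (n,) int class codes
    sample_weights: np.ndarray
    end_index: np.ndarray      # grid index of each window's last sample

    @property
    def n(self) -> int:
        return len(self.targets)

    def subset(self, idx) -> "SequenceBatch":
        return SequenceBatch(self.inputs[idx], self.targets[idx],
                             self.sample_weights[idx], self.end_index[idx])


def class_weights(targets: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """Per-window weight = total / (n_classes * class size)."""
    counts = np.bincount(targets, minlength=n_classes)
    w = np.zeros(n_classes)
    present = counts > 0
    w[present] = len(targets) / (n_classes * counts[present])
    return w[targets]


def build_sequences(table: FeatureTable, labels: np.ndarray) -> SequenceBatch:
    """Sliding 24-sample windows over valid feature rows.

    Windows overlapping any invalid row (residual missing data) are
    dropped; the target of a window ending at k is the label at k.
    """
    X = table.values
    n, F = X.shape
    valid = table.valid_mask
    ends, wins, ys = [], [], []
    for k in range(WINDOW - 1, n):
        if valid[k - WINDOW + 1: k + 1].all():
            wins.append(X[k - WINDOW + 1: k + 1])
            ys.append(labels[k])
            ends.append(k)
    if not wins:
        raise ValueError("no complete 24-sample window")
    inputs = np.stack(wins)
    targets = np.asarray(ys, dtype=int)
    return SequenceBatch(inputs=inputs, targets=targets,
                         sample_weights=class_weights(targets),
                         end_index=np.asarray(ends))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class DetectorConfig:
    lstm_units: int = 64
    dense_units: int = 32
    conv_filters: tuple = (32, 64)
    kernel: int = 3
    pool: int = 2
    dropout: float = 0.2
    recurrent_dropout: float = 0.2
    l1: float = 1e-4
    lr: float = 1e-3
    lr_conv: float = 5e-4
    epochs: int = 100
    patience: int = 10
    batch_frac: float = 0.02
    folds: int = 6
    train_frac: float = 0.875
    seeds: int = 5

    def learning_rate(self, architecture: str) -> float:
        return self.lr if architecture == "lstm" else self.lr_conv


def build_model(architecture: str, input_shape: tuple,
                cfg: DetectorConfig | None = None, seed: int = 0) -> nn.Sequential:
    """Assemble one of the four detector architectures for input
    windows of shape (lags, features)."""
    cfg = cfg or DetectorConfig()
    T, F = input_shape
    rng = np.random.default_rng(seed)
    u, d = cfg.lstm_units, cfg.dense_units
    f1, f2 = cfg.conv_filters
    k, pool = cfg.kernel, cfg.pool
    if architecture == "lstm":
        layers = [
            nn.Masking(0.0),
            nn.LSTM(F, u, recurrent_dropout=cfg.recurrent_dropout, rng=rng),
            nn.Dense(u, d, activation="relu", rng=rng),
            nn.Dropout(cfg.dropout, rng=rng),
            nn.Dense(d, 4, rng=rng),
        ]
    elif architecture == "conv1d_lstm":
        t1 = (T - k + 1) // pool
        t2 = (t1 - k + 1) // pool
        if t2 < 1:
            raise ValueError("window too short for the conv/pool stack")
        layers = [
            nn.Conv1D(F, f1, k, rng=rng), nn.MaxPool1D(pool),
            nn.Conv1D(f1, f2, k, rng=rng), nn.MaxPool1D(pool),
            nn.LSTM(f2, u, rng=rng),
            nn.Dense(u, d, activation="relu", rng=rng),
            nn.Dense(d, 4, rng=rng),
        ]
    elif architecture == "convlstm2d":
        layers = [
            nn.ConvLSTM(F, u, rng=rng),
            nn.Dropout(cfg.dropout, rng=rng),
            nn.Dense(u, d, activation="relu", rng=rng),
            nn.Dense(d, 4, rng=rng),
        ]
    elif architecture == "conv1d_bilstm":
        layers = [
            nn.Conv1D(F, f1, k, rng=rng), nn.MaxPool1D(pool),
            nn.Conv1D(f1, f2, k, rng=rng), nn.MaxPool1D(pool),
            nn.BiLSTM(f2, u, rng=rng),
            nn.Dense(2 * u, d, activation="relu", rng=rng),
            nn.Dense(d, 4, rng=rng),
        ]
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    return nn.Sequential(layers, l1=cfg.l1)


def recurrent_param_count(model: nn.Sequential) -> int:
    return sum(p.size for lay in model.layers
               if isinstance(lay, (nn.LSTM, nn.BiLSTM)) for p in lay.params)


@dataclass
class TrainedDetector:
    architecture: str
    model: nn.Sequential
    cfg: DetectorConfig
    seed: int
    history: list = field(default_factory=list)


def predict_events(det: TrainedDetector, batch: SequenceBatch):
    """Class probabilities (rows on the 4-simplex) and argmax classes
    (ties broken toward the lower class index)."""
    proba = det.model.predict_proba(batch.inputs)
    return proba, proba.argmax(axis=1)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Accuracy, weighted F1, per-class precision/recall/F1 and the 4x4
    confusion matrix (rows = true class)."""
    if len(pred) == 0 or len(pred) != len(truth):
        raise ValueError("empty or mismatched prediction/truth")
    labels = list(range(4))
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, pred, labels=labels, zero_division=0)
    weighted_f1 = float(np.sum(f1 * support) / support.sum())
    return {
        "accuracy": float(accuracy_score(truth, pred)),
        "weighted_f1": weighted_f1,
        "precision": prec.tolist(),
        "recall": rec.tolist(),
        "f1": f1.tolist(),
        "support": support.tolist(),
        "confusion": confusion_matrix(truth, pred, labels=labels).tolist(),
    }


def chronological_split(batch: SequenceBatch, train_frac: float = 0.875):
    """Development/test split at the chronological cut point (free-living
    data: the test set is the most recent 12.5%)."""
    order = np.argsort(batch.end_index, kind="stable")
    cut = int(round(train_frac * batch.n))
    return batch.subset(order[:cut]), batch.subset(order[cut:])


def train_detector(batch: SequenceBatch, architecture: str,
                   cfg: DetectorConfig | None = None, seed: int = 0,
                   verbose: bool = False) -> tuple[list, dict]:
    """Full training protocol for one architecture.

    Chronological development/test split, stratified k-fold CV inside
    the development split, ``cfg.seeds`` seeded trainings per fold.
    Returns the trained detectors and a report with per-fold validation
    metrics (mean and SD over folds and seeds) plus test metrics of the
    last-fold models.
    """
    cfg = cfg or DetectorConfig()
    dev, test = chronological_split(batch, cfg.train_frac)
    counts = np.bincount(dev.targets, minlength=4)
    n_splits = int(min(cfg.folds, counts[counts > 0].min()))
    if n_splits < 2:
        raise ValueError("a class has fewer than 2 development windows; "
                         "cannot stratify folds")
    if n_splits < cfg.folds:
        log.warning("train_detector: reduced CV folds to %d (smallest class)",
                    n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    lr = cfg.learning_rate(architecture)
    batch_size = max(8, int(round(cfg.batch_frac * dev.n)))
    detectors = []
    fold_acc, fold_f1 = [], []
    for fold, (tr, va) in enumerate(skf.split(dev.inputs, dev.targets)):
        for s in range(cfg.seeds):
            mseed = (seed * 1000 + fold * 10 + s) % (2 ** 31)
            model = build_model(architecture, batch.inputs.shape[1:], cfg,
                                seed=mseed)
            hist = model.fit(
                dev.inputs[tr], dev.targets[tr],
                sample_weight=dev.sample_weights[tr],
                epochs=cfg.epochs, batch_size=batch_size, lr=lr, seed=mseed,
                x_val=dev.inputs[va], y_val=dev.targets[va],
                patience=cfg.patience, verbose=verbose)
            det = TrainedDetector(architecture, model, cfg, mseed, hist)
            _, pred = predict_events(det, dev.subset(va))
            m = evaluate(pred, dev.targets[va])
            fold_acc.append(m["accuracy"])
            fold_f1.append(m["weighted_f1"])
            detectors.append(det)
    test_metrics = None
    if test.n:
        _, pred = predict_events(detectors[-1], test)
        test_metrics = evaluate(pred, test.targets)
    report = {
        "cv_accuracy_mean": float(np.mean(fold_acc)),
        "cv_accuracy_sd": float(np.std(fold_acc)),
        "cv_weighted_f1_mean": float(np.mean(fold_f1)),
        "cv_weighted_f1_sd": float(np.std(fold_f1)),
        "n_models": len(detectors),
        "test": test_metrics,
    }
    return detectors, report
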