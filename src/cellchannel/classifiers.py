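"""Classifiers: the CNN with its training protocol, and SVM-on-cell-size.

Training protocol: Adam (alpha 1e-4, beta1 0.9, beta2 0.999, eps 1e-8),
batch size 32, a stratified 10% validation split, early stopping when the
validation loss has not decreased for 5 consecutive epochs (restoring the
best-seen parameters), and a hard cap of 30 epochs.  The Adam parameter
list also records an ``eta = 1.0`` learning-rate multiplier; with alpha as
the step size it is an identity no-op and is kept only in the config.

The baseline classifier is an RBF-kernel SVM (kernel coefficient gamma = 1)
on the cell size alone; areas are z-scored with training-fold statistics so
that a unit kernel coefficient acts on an order-1 feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from cellchannel.nn import Adam, SmallCNN, cross_entropy

logger = logging.getLogger(__name__)


# ---- the activation / loss primitives -------------------------------------

def relu(x):
    """Elementwise max(x, 0)."""
    return np.maximum(np.asarray(x), 0)


def softmax(x):
    """Shift-invariant softmax over the last axis."""
    x = np.asarray(x, dtype=np.float64)
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def bce_loss(y, y_hat, clamp: float = 1e-12):
    """Binary cross-entropy -y*log(p) - (1-y)*log(1-p), with p clamped to
    [clamp, 1-clamp]; zero at p == y."""
    p = np.clip(np.asarray(y_hat, dtype=np.float64), clamp, 1.0 - clamp)
    y = np.asarray(y, dtype=np.float64)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


# ---- specs -----------------------------------------------------------------

@dataclass(frozen=True)
class CNNSpec:
    """Architecture: widths double when the input has >= 2 channels."""

    in_channels: int = 1
    input_size: int = 150
    fc_nodes: int = 2000
    dropout: float = 0.1

    @property
    def conv_widths(self) -> tuple[int, ...]:
        return (16, 16, 32, 32) if self.in_channels == 1 else (32, 32, 64, 64)


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    eta: float = 1.0          # recorded; identity multiplier on the step
    batch_size: int = 32
    validation_fraction: float = 0.1
    patience: int = 5
    max_epochs: int = 30
    init_seed: int = 0
    data_seed: int = 1        # shuffling and the validation split


class EarlyStopper:
    """Patience-based stopping on the validation loss.

    ``update`` returns True when the loss has failed to decrease for
    ``patience`` consecutive epochs; the best epoch (1-based) and loss are
    tracked so the caller can restore the best parameter state.
    """

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        self.epoch += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


@dataclass
class TrainedCNN:
    model: SmallCNN
    spec: CNNSpec
    train_spec: TrainSpec
    epochs_run: int
    best_epoch: int
    history: list[dict] = field(default_factory=list)  # epoch, train/val loss


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Index split (train, val) with per-class proportional sampling."""
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.append(rng.permutation(idx)[:n_val])
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(len(y)), val)
    return train, val


def train_cnn(x: np.ndarray, y: np.ndarray, spec: CNNSpec | None = None,
              train_spec: TrainSpec | None = None) -> TrainedCNN:
    """Fit the CNN; returns the parameter state with the smallest validation
    loss seen.  ``x`` is (N, C, 150, 150) preprocessed float input, ``y``
    integer class labels {0, 1}.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    if spec is None:
        spec = CNNSpec(in_channels=x.shape[1], input_size=x.shape[2])
    ts = train_spec or TrainSpec()
    data_rng = np.random.default_rng(ts.data_seed)
    tr_idx, val_idx = _stratified_split(y, ts.validation_fraction, data_rng)
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    model = SmallCNN(in_channels=spec.in_channels, input_size=spec.input_size,
                     fc_nodes=spec.fc_nodes, dropout=spec.dropout,
                     seed=ts.init_seed)
    opt = Adam(model.params, lr=ts.learning_rate * ts.eta, beta1=ts.beta1,
               beta2=ts.beta2, eps=ts.eps)
    drop_rng = np.random.default_rng(ts.init_seed + 1)
    stopper = EarlyStopper(patience=ts.patience)
    best_state = model.get_state()
    history = []

    for epoch in range(1, ts.max_epochs + 1):
        order = data_rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), ts.batch_size):
            batch = order[i:i + ts.batch_size]
            probs, cache = model.forward(x_tr[batch], rng=drop_rng)
            loss = cross_entropy(probs, y_tr[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i}")
            grads = model.backward(probs, y_tr[batch], cache)
            opt.step(model.params, grads)
            losses.append(loss)
        val_probs = model.predict_proba(x_val, batch_size=ts.batch_size)
        val_loss = cross_entropy(val_probs, y_val)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss)})
        improved = val_loss < stopper.best_loss
        stop = stopper.update(val_loss)
        if improved:
            best_state = model.get_state()
        logger.debug("epoch %d: train %.4f val %.4f", epoch,
                     history[-1]["train_loss"], val_loss)
        if stop:
            break

    model.set_state(best_state)
    return TrainedCNN(model=model, spec=spec, train_spec=ts,
                      epochs_run=stopper.epoch, best_epoch=stopper.best_epoch,
                      history=history)


def predict_proba(trained: TrainedCNN, x: np.ndarray) -> np.ndarray:
    """Per-cell class probabilities (inference mode, dropout off)."""
    x = np.asarray(x, dtype=np.float32)
    if x.shape[1] != trained.spec.in_channels:
        raise ValueError(
            f"channel mismatch: model expects {trained.spec.in_channels} "
            f"channels, input has {x.shape[1]}")
    return trained.model.predict_proba(x, batch_size=trained.train_spec.batch_size)


@dataclass
class SizeSVM:
    """RBF-kernel SVM over z-scored cell areas, exposing decision values."""

    svc: SVC
    mean: float
    sd: float

    def decision_values(self, areas) -> np.ndarray:
        z = (np.asarray(areas, dtype=np.float64).reshape(-1, 1) - self.mean) / self.sd
        return self.svc.decision_function(z)


def train_svm_size(areas, labels) -> SizeSVM:
    """Fit the cell-size baseline.  ``labels`` are integer classes {0, 1};
    the decision function is oriented so positive values favour class 1."""
    areas = np.asarray(areas, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set contains a single class")
    mean = float(areas.mean())
    sd = float(areas.std())
    if sd == 0:
        sd = 1.0
    svc = SVC(kernel="rbf", gamma=1.0)
    svc.fit(((areas - mean) / sd).reshape(-1, 1), labels)
    return SizeSVM(svc=svc, mean=mean, sd=sd)
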