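"""Tissue classifiers: one-hidden-layer MLP and a three-conv-block CNN.

Both architectures map a log2(TPM+1) expression vector to probability-like
scores over tissue classes.  The MLP is input -> dense(128) -> batch norm ->
ReLU -> dropout -> dense(classes).  The CNN first places genes row-major into
a square grid (zero padding at the tail), then applies three convolution +
max-pool + batch-norm + ReLU blocks, dropout, global average pooling with
batch norm and ReLU, and a final dense layer.

Training uses Adam on cross-entropy with L2 regularization, per-epoch class
up-sampling (every class is resampled with replacement to the majority count)
and a reduce-on-plateau learning-rate schedule: when the training loss has
not improved for ``lr_patience`` consecutive epochs, the learning rate is
multiplied by ``lr_factor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn

DEFAULT_CNN_CHANNELS = (64, 128, 256)


@dataclass
class ModelConfig:
    arch: str  # "MLP" or "CNN"
    n_genes: int
    n_classes: int
    hidden_units: int = 128
    channels: tuple = DEFAULT_CNN_CHANNELS
    kernel_sizes: tuple = (5, 5, 3)
    pool_kernel: int = 2
    grid_side: int | None = None
    dropout_p: float = 0.25
    lr: float | None = None  # default depends on arch
    l2_lambda: float = 0.001
    batch_size: int = 256
    lr_patience: int = 5
    lr_factor: float = 0.25
    loss_improve_tol: float = 1e-4
    max_epochs: int = 50
    seed: int = 0
    gene_order: np.ndarray | None = None  # permutation; identity if None

    def __post_init__(self):
        if self.arch not in ("MLP", "CNN"):
            raise ValueError(f"unknown architecture {self.arch!r}")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.lr is None:
            self.lr = 0.001 if self.arch == "MLP" else 0.0006
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.arch == "CNN":
            if self.grid_side is None:
                self.grid_side = math.isqrt(self.n_genes - 1) + 1 if self.n_genes > 1 else 1
            if self.grid_side**2 < self.n_genes:
                raise ValueError("grid_side^2 must cover n_genes")
            if self.grid_side // self.pool_kernel ** len(self.channels) < 1:
                raise ValueError("grid too small for the pooling stages")
        if self.gene_order is None:
            self.gene_order = np.arange(self.n_genes)
        else:
            self.gene_order = np.asarray(self.gene_order)
            if not np.array_equal(np.sort(self.gene_order), np.arange(self.n_genes)):
                raise ValueError("gene_order must be a permutation of range(n_genes)")


def random_gene_order(n_genes: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).permutation(n_genes)


def reshape_to_grid(sample: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Place one expression vector into the CNN input grid (zero pad at tail)."""
    sample = np.asarray(sample)
    if sample.shape[-1] != config.n_genes:
        raise ValueError(f"expected {config.n_genes} genes, got {sample.shape[-1]}")
    layer = nn.GridReshape(config.gene_order, config.grid_side)
    out, _ = layer.forward(sample.reshape(1, -1), nn.Context())
    return out[0, 0]


def flatten_from_grid(grid: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Inverse of :func:`reshape_to_grid`."""
    flat = np.asarray(grid).reshape(-1)[: config.n_genes]
    out = np.empty(config.n_genes)
    out[config.gene_order] = flat
    return out


@dataclass
class TrainedClassifier:
    config: ModelConfig
    net: nn.Sequential
    class_list: list
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_classes(self):
        return len(self.class_list)

    def class_index(self, label):
        try:
            return self.class_list.index(label)
        except ValueError:
            raise KeyError(f"unknown class {label!r}") from None

    def logits(self, X, dropout_rng=None, replay_masks=None, record_masks=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ctx = nn.Context(train=False, rng=dropout_rng, record_masks=record_masks, replay_masks=replay_masks)
        return self.net.forward(X, ctx)

    def predict_proba(self, X):
        z, _ = self.logits(X)
        return nn.softmax(z)

    def predict(self, X):
        p = self.predict_proba(X)
        return [self.class_list[i] for i in p.argmax(axis=1)]


def build_model(config: ModelConfig) -> TrainedClassifier:
    rng = np.random.default_rng(config.seed)
    if config.arch == "MLP":
        layers = [
            nn.Dense(config.n_genes, config.hidden_units, rng),
            nn.BatchNorm(config.hidden_units),
            nn.ReLU(),
            nn.Dropout(config.dropout_p),
            nn.Dense(config.hidden_units, config.n_classes, rng),
        ]
    else:
        layers = [nn.GridReshape(config.gene_order, config.grid_side)]
        c_in = 1
        for c_out, k in zip(config.channels, config.kernel_sizes):
            layers += [
                nn.Conv2d(c_in, c_out, k, rng),
                nn.MaxPool2d(config.pool_kernel),
                nn.BatchNorm(c_out, conv=True),
                nn.ReLU(),
            ]
            c_in = c_out
        layers += [
            nn.Dropout(config.dropout_p),
            nn.GlobalAvgPool(),
            nn.BatchNorm(c_in),
            nn.ReLU(),
            nn.Dense(c_in, config.n_classes, rng),
        ]
    return TrainedClassifier(config=config, net=nn.Sequential(layers), class_list=[])


def upsample_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-epoch balanced resampling: every class contributes the majority count."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    chosen = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        chosen.append(rng.choice(idx, size=target, replace=True))
    out = np.concatenate(chosen)
    rng.shuffle(out)
    return out


def train(matrix, config: ModelConfig, model: TrainedClassifier | None = None) -> TrainedClassifier:
    """Train a classifier on an ExpressionMatrix (values on log2(TPM+1) scale)."""
    X = np.asarray(matrix.values, dtype=float)
    y_labels = np.asarray(matrix.tissue_labels)
    classes = sorted(set(y_labels))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    y = np.array([classes.index(t) for t in y_labels])

    if model is None:
        model = build_model(config)
    model.class_list = classes
    net = model.net
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(net, lr=config.lr, l2_lambda=config.l2_lambda)

    best_loss = np.inf
    stall = 0
    records = []
    for epoch in range(config.max_epochs):
        idx = upsample_indices(y, rng)
        losses, correct, total = [], 0, 0
        for start in range(0, len(idx), config.batch_size):
            b = idx[start : start + config.batch_size]
            xb, yb = X[b], y[b]
            ctx = nn.Context(train=True, rng=rng)
            z, caches = net.forward(xb, ctx)
            p = nn.softmax(z)
            loss = -np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-12))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            g = p.copy()
            g[np.arange(len(yb)), yb] -= 1.0
            g /= len(yb)
            net.backward(g, caches, want_param_grads=True)
            opt.step()
            losses.append(loss)
            correct += int((z.argmax(axis=1) == yb).sum())
            total += len(yb)
        epoch_loss = float(np.mean(losses))
        records.append({"epoch": epoch, "loss": epoch_loss, "accuracy": correct / total, "lr": opt.lr})
        if epoch_loss < best_loss - config.loss_improve_tol:
            best_loss = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_patience:
                opt.lr *= config.lr_factor
                stall = 0
    model.history = pd.DataFrame.from_records(records)
    return model


def accuracy(model: TrainedClassifier, matrix) -> float:
    pred = model.predict(np.asarray(matrix.values, dtype=float))
    return float(np.mean(np.asarray(pred) == np.asarray(matrix.tissue_labels)))


def cross_validate(matrix, config: ModelConfig, n_folds: int = 5) -> dict:
    """Stratified k-fold; metrics on the pooled held-out predictions."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(matrix.tissue_labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < n_folds]
    if len(small):
        raise ValueError(f"classes smaller than n_folds={n_folds}: {list(small)}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    pooled_true, pooled_pred = [], []
    fold_assignment = np.empty(len(labels), dtype=int)
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_assignment[te] = f
        sub_cfg = replace(config, seed=config.seed + 101 * (f + 1))
        model = train(matrix.subset(tr), sub_cfg)
        pred = model.predict(np.asarray(matrix.values, dtype=float)[te])
        pooled_true.extend(labels[te])
        pooled_pred.extend(pred)
    pooled_true = np.asarray(pooled_true)
    pooled_pred = np.asarray(pooled_pred)
    per_class = {
        c: float(np.mean(pooled_pred[pooled_true == c] == c)) for c in classes
    }
    return {
        "accuracy": float(np.mean(pooled_true == pooled_pred)),
        "per_class_accuracy": per_class,
        "fold_assignment": fold_assignment,
        "n_folds": n_folds,
    }


def class_score_gradient(model: TrainedClassifier, sample, target_class, dropout_enabled=False, seed=None):
    """Gradient of the pre-softmax score of ``target_class`` w.r.t. each gene.

    With ``dropout_enabled`` a single mask per call is drawn from ``seed`` and
    applied consistently in the forward and backward passes.
    """
    t = target_class if isinstance(target_class, (int, np.integer)) else model.class_index(target_class)
    rng = np.random.default_rng(seed) if dropout_enabled else None
    z, caches = model.logits(sample, dropout_rng=rng)
    g_out = np.zeros_like(z)
    g_out[:, t] = 1.0
    return model.net.backward(g_out, caches)[0]
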