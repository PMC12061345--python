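"""Classifiers over 270-dimensional binary feature vectors.

Three model kinds:

* ``lr``  — single affine layer + logistic link, trained by Adam on mean
  sigmoid focal cross-entropy with a stratified 20% validation split;
* ``knn`` — exact (brute-force) k-nearest-neighbour majority vote under
  Euclidean distance, probability = positive-neighbour fraction;
* ``cnn`` — 1-D convolution (ReLU) over the catalog-ordered feature axis,
  local max pooling, single logistic output unit; same loss and optimizer.

All training is deterministic under a fixed seed.  Implemented directly in
NumPy so the loss, optimizer and architectures are exactly the stated ones
and runs are reproducible without a deep-learning runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

N_FEATURES = 270

MODEL_KINDS = ("lr", "knn", "cnn")


@dataclass(frozen=True)
class ModelConfig:
    model_kind: str = "lr"
    threshold: float = 0.50
    validation_fraction: float = 0.20
    seed: int = 0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    knn_k: int = 5
    cnn_filters: int = 32
    cnn_kernel: int = 3
    cnn_pool_size: int = 2
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int | None = 10  # None disables early stopping

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be odd and >= 1")


@dataclass
class PredictionResult:
    visit_id: str
    probability: float
    label: int  # 1 iff probability >= threshold (ties positive)


@dataclass
class TrainedModel:
    config: ModelConfig
    parameters: dict  # learned state, arrays as np.ndarray
    catalog_version: str
    training_history: list[dict] = field(default_factory=list)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        expected = self.parameters["n_features"]
        if X.shape[1] != expected:
            raise ValueError(
                f"feature width {X.shape[1]} does not match model trained on "
                f"{expected} features (catalog {self.catalog_version})"
            )
        kind = self.config.model_kind
        if kind == "lr":
            return _sigmoid(X @ self.parameters["w"] + self.parameters["b"])
        if kind == "cnn":
            return _cnn_forward(X, self.parameters, self.config.cnn_pool_size)[0]
        if kind == "knn":
            return _knn_proba(X, self.parameters["X_train"], self.parameters["y_train"],
                              self.config.knn_k)
        raise ValueError(f"unknown model kind {kind!r}")

    # -- persistence (self-describing JSON archive) -------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "catalog_version": self.catalog_version,
            "training_history": self.training_history,
            "parameters": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.parameters.items()
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        params = {
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in payload["parameters"].items()
        }
        return cls(
            config=ModelConfig(**payload["config"]),
            parameters=params,
            catalog_version=payload["catalog_version"],
            training_history=payload["training_history"],
        )


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def focal_loss(z: np.ndarray, y: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    """Per-sample sigmoid focal cross-entropy from logits.

    FL = -alpha * y * (1-p)^gamma * log(p) - (1-alpha) * (1-y) * p^gamma * log(1-p)
    with p = sigmoid(z); computed via softplus for numerical stability.
    """
    p = _sigmoid(z)
    return (
        alpha * y * (1.0 - p) ** gamma * _softplus(-z)
        + (1.0 - alpha) * (1.0 - y) * p ** gamma * _softplus(z)
    )


def focal_loss_grad(z: np.ndarray, y: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    """d(focal loss)/d(logit), per sample (analytic)."""
    p = _sigmoid(z)
    g_pos = -alpha * (1.0 - p) ** gamma * (gamma * p * _softplus(-z) + (1.0 - p))
    g_neg = (1.0 - alpha) * p ** gamma * (gamma * (1.0 - p) * _softplus(z) + p)
    return y * g_pos + (1.0 - y) * g_neg


# ---------------------------------------------------------------------------
# Adam optimizer
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, shapes: list[tuple[int, ...]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# shared training scaffolding
# ---------------------------------------------------------------------------

def _validate_training_inputs(X: np.ndarray, y: np.ndarray, require_both_classes=True):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if require_both_classes and len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; cannot train a classifier")
    return X, y


def _stratified_validation_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Indices (train, val); per-class proportional allocation, seeded."""
    val_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(fraction * len(idx)))) if len(idx) > 1 else 0
        perm = rng.permutation(len(idx))
        val_idx.extend(idx[perm[:n_val]].tolist())
    val = np.array(sorted(val_idx), dtype=int)
    train = np.setdiff1d(np.arange(len(y)), val)
    return train, val


def _minibatch_train(X, y, config, init_params, forward_backward, rng):
    """Generic Adam minibatch loop with validation monitoring + early stop.

    ``forward_backward(params, Xb, yb) -> (losses, grads)``;
    returns (best params, history).
    """
    tr_idx, va_idx = _stratified_validation_split(y, config.validation_fraction, rng)
    X_tr, y_tr, X_va, y_va = X[tr_idx], y[tr_idx], X[va_idx], y[va_idx]
    params = [p.copy() for p in init_params]
    adam = _Adam([p.shape for p in params], config.learning_rate)
    history: list[dict] = []
    best_val, best_params, patience = np.inf, [p.copy() for p in params], 0
    n = len(y_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            losses, grads = forward_backward(params, X_tr[batch], y_tr[batch])
            epoch_loss += float(np.sum(losses))
            adam.step(params, grads)
        train_loss = epoch_loss / max(n, 1)
        if len(y_va):
            val_losses, _ = forward_backward(params, X_va, y_va)
            val_loss = float(np.mean(val_losses))
        else:
            val_loss = train_loss  # degenerate split: monitor training loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val, best_params, patience = val_loss, [p.copy() for p in params], 0
        else:
            patience += 1
            if config.early_stop_patience is not None and patience >= config.early_stop_patience:
                break
    return best_params, history


# ---------------------------------------------------------------------------
# logistic regression (single dense layer + sigmoid + focal loss)
# ---------------------------------------------------------------------------

def train_lr(features: np.ndarray, labels: np.ndarray, config: ModelConfig,
             catalog_version: str = "v1") -> TrainedModel:
    X, y = _validate_training_inputs(features, labels)
    rng = np.random.default_rng(config.seed)
    d = X.shape[1]
    init = [np.zeros(d), np.zeros(1)]

    def fb(params, Xb, yb):
        w, b = params
        z = Xb @ w + b[0]
        losses = focal_loss(z, yb, config.focal_alpha, config.focal_gamma)
        dz = focal_loss_grad(z, yb, config.focal_alpha, config.focal_gamma) / len(yb)
        return losses, [Xb.T @ dz, np.array([dz.sum()])]

    (w, b), history = _minibatch_train(X, y, config, init, fb, rng)
    return TrainedModel(
        config=config,
        parameters={"w": w, "b": float(b[0]), "n_features": d},
        catalog_version=catalog_version,
        training_history=history,
    )


# ---------------------------------------------------------------------------
# k-nearest neighbours (exact, deterministic tie-breaking by index)
# ---------------------------------------------------------------------------

def _knn_proba(X: np.ndarray, X_train: np.ndarray, y_train: np.ndarray, k: int) -> np.ndarray:
    # squared Euclidean; exact for binary features (all terms are small ints)
    d2 = (
        (X ** 2).sum(axis=1)[:, None]
        + (X_train ** 2).sum(axis=1)[None, :]
        - 2.0 * (X @ X_train.T)
    )
    # stable sort: equidistant neighbours resolved by training-set order
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return y_train[nearest].mean(axis=1)


def train_knn(features: np.ndarray, labels: np.ndarray, config: ModelConfig,
              catalog_version: str = "v1") -> TrainedModel:
    X, y = _validate_training_inputs(features, labels, require_both_classes=False)
    if config.knn_k > X.shape[0]:
        raise ValueError(f"knn_k={config.knn_k} exceeds training size {X.shape[0]}")
    return TrainedModel(
        config=config,
        parameters={"X_train": X, "y_train": y, "n_features": X.shape[1]},
        catalog_version=catalog_version,
        training_history=[],
    )


# ---------------------------------------------------------------------------
# 1-D CNN (conv + ReLU -> global max pool -> dense sigmoid)
# ---------------------------------------------------------------------------

def _cnn_forward(X: np.ndarray, params: dict, pool: int):
    """conv(ReLU) -> local max pool (non-overlapping) -> flatten -> dense."""
    W1, b1 = params["W1"], params["b1"]  # (F, k), (F,)
    w2, b2 = params["w2"], params["b2"]  # (L2*F,), scalar
    k = W1.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (n, L, k)
    Z1 = windows @ W1.T + b1  # (n, L, F)
    A1 = np.maximum(Z1, 0.0)
    n, L, F = A1.shape
    L2 = L // pool  # trailing remainder dropped, as is conventional
    blocks = A1[:, : L2 * pool, :].reshape(n, L2, pool, F)
    argmax = blocks.argmax(axis=2)  # (n, L2, F)
    pooled = np.take_along_axis(blocks, argmax[:, :, None, :], axis=2)[:, :, 0, :]
    flat = pooled.reshape(n, L2 * F)
    z2 = flat @ w2 + b2
    return _sigmoid(z2), (windows, Z1, blocks, argmax, flat, z2)


def train_cnn(features: np.ndarray, labels: np.ndarray, config: ModelConfig,
              catalog_version: str = "v1") -> TrainedModel:
    X, y = _validate_training_inputs(features, labels)
    d = X.shape[1]
    if config.cnn_kernel > d:
        raise ValueError(f"cnn_kernel={config.cnn_kernel} wider than feature axis {d}")
    rng = np.random.default_rng(config.seed)
    F, kw, pool = config.cnn_filters, config.cnn_kernel, config.cnn_pool_size
    L2 = (d - kw + 1) // pool
    init = [
        rng.normal(0.0, np.sqrt(2.0 / kw), size=(F, kw)),  # He init for ReLU conv
        np.zeros(F),
        np.zeros(L2 * F),  # zero-init output layer: untrained model outputs 0.5
        np.zeros(1),
    ]

    def fb(params, Xb, yb):
        W1, b1, w2, b2 = params
        p, (windows, Z1, blocks, argmax, flat, z2) = _cnn_forward(
            Xb, {"W1": W1, "b1": b1, "w2": w2, "b2": b2[0]}, pool
        )
        losses = focal_loss(z2, yb, config.focal_alpha, config.focal_gamma)
        dz2 = focal_loss_grad(z2, yb, config.focal_alpha, config.focal_gamma) / len(yb)
        dw2 = flat.T @ dz2
        db2 = np.array([dz2.sum()])
        n = Xb.shape[0]
        dflat = dz2[:, None] * w2[None, :]  # (n, L2*F)
        dpooled = dflat.reshape(n, L2, F)
        dblocks = np.zeros_like(blocks)
        np.put_along_axis(dblocks, argmax[:, :, None, :], dpooled[:, :, None, :], axis=2)
        dA1 = np.zeros_like(Z1)
        dA1[:, : L2 * pool, :] = dblocks.reshape(n, L2 * pool, F)
        dZ1 = dA1 * (Z1 > 0.0)
        dW1 = np.einsum("ntf,ntk->fk", dZ1, windows)
        db1 = dZ1.sum(axis=(0, 1))
        return losses, [dW1, db1, dw2, db2]

    (W1, b1, w2, b2), history = _minibatch_train(X, y, config, init, fb, rng)
    return TrainedModel(
        config=config,
        parameters={"W1": W1, "b1": b1, "w2": w2, "b2": float(b2[0]), "n_features": d},
        catalog_version=catalog_version,
        training_history=history,
    )


# ---------------------------------------------------------------------------
# dispatch and prediction
# ---------------------------------------------------------------------------

_TRAINERS = {"lr": train_lr, "knn": train_knn, "cnn": train_cnn}


def train(features: np.ndarray, labels: np.ndarray, config: ModelConfig,
          catalog_version: str = "v1") -> TrainedModel:
    return _TRAINERS[config.model_kind](features, labels, config, catalog_version)


def predict(model: TrainedModel, features: np.ndarray,
            visit_ids: list[str] | None = None) -> list[PredictionResult]:
    """Thresholded predictions; a probability exactly at threshold is positive."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    probs = model.predict_proba(X)
    if visit_ids is None:
        visit_ids = [str(i) for i in range(len(probs))]
    if len(visit_ids) != len(probs):
        raise ValueError("visit_ids and feature rows disagree in length")
    thr = model.config.threshold
    return [
        PredictionResult(vid, float(p), int(p >= thr))
        for vid, p in zip(visit_ids, probs)
    ]
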