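"""Twin-tower convolutional pair classifier over fused histogram tensors.

Two convolutional towers with identical architecture but separate weights
process the lncRNA and miRNA 20x20x4 tensors; their flattened outputs are
concatenated and passed through dense layers to a single sigmoid unit that
scores interaction probability. Each tower block is conv(3x3, stride 1,
ReLU) -> batch norm -> dropout; there is no pooling. A pair is called an
interaction when the probability is strictly greater than 0.5.

Default stack: conv(32) -> BN -> dropout(.25) -> conv(64) -> BN ->
dropout(.25) per tower, concat, dense(128, ReLU) -> dropout(.5) ->
dense(1, sigmoid); binary cross-entropy, Adam (lr 1e-3), batch 64, up to
50 epochs with early stopping (patience 10) on a validation split.
Histogram counts are log1p-compressed on the way in — corner cells can hold
hundreds of points while most cells hold a few, and raw counts at that
spread destabilize the early epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    ReLU,
    bce_loss_and_grad,
    sigmoid,
    F32,
)

__all__ = ["ModelConfig", "Prediction", "TwinTowerClassifier", "build_model", "train", "predict"]

DECISION_THRESHOLD = 0.5


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters of the pair classifier."""

    conv_blocks: tuple[int, ...] = (32, 64)
    kernel: int = 3
    dropout_rate: float = 0.25
    dense_units: tuple[int, ...] = (128,)
    dense_dropout: float = 0.5
    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 1e-3
    validation_fraction: float = 0.15
    patience: int = 10
    seed: int = 0


@dataclass(frozen=True)
class Prediction:
    """Scored lncRNA-miRNA pair; ``call`` is True iff probability > 0.5."""

    lnc_id: str
    mir_id: str
    probability: float
    call: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "call", self.probability > DECISION_THRESHOLD)


class _Tower:
    def __init__(self, in_shape, cfg: ModelConfig, rng):
        h, w, c = in_shape
        self.layers = []
        for n_filt in cfg.conv_blocks:
            self.layers += [
                Conv2D(c, n_filt, cfg.kernel, rng),
                ReLU(),
                BatchNorm(n_filt),
                Dropout(cfg.dropout_rate, rng),
            ]
            h -= cfg.kernel - 1
            w -= cfg.kernel - 1
            c = n_filt
            if h < 1 or w < 1:
                raise ValueError("input too small for the configured conv stack")
        self.layers.append(Flatten())
        self.out_dim = h * w * c

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d):
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class _TwinTowerNet:
    """The full network: two towers, concatenation, dense head."""

    def __init__(self, in_shape: tuple[int, int, int], cfg: ModelConfig):
        rng = np.random.Generator(np.random.PCG64(cfg.seed))
        self.cfg = cfg
        self.tower_lnc = _Tower(in_shape, cfg, rng)
        self.tower_mir = _Tower(in_shape, cfg, rng)
        self.head = []
        n_in = self.tower_lnc.out_dim + self.tower_mir.out_dim
        for units in cfg.dense_units:
            self.head += [Dense(n_in, units, rng), ReLU(), Dropout(cfg.dense_dropout, rng)]
            n_in = units
        self.head.append(Dense(n_in, 1, rng))

    def all_layers(self):
        return self.tower_lnc.layers + self.tower_mir.layers + self.head

    def parameters(self):
        return [p for l in self.all_layers() for p in l.params()]

    def gradients(self):
        return [g for l in self.all_layers() for g in l.grads()]

    def forward(self, x_lnc, x_mir, train: bool) -> np.ndarray:
        za = self.tower_lnc.forward(x_lnc, train)
        zb = self.tower_mir.forward(x_mir, train)
        self._split = za.shape[1]
        z = np.concatenate([za, zb], axis=1)
        for layer in self.head:
            z = layer.forward(z, train)
        return z[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        d = dlogit[:, None].astype(F32)
        for layer in reversed(self.head):
            d = layer.backward(d)
        self.tower_lnc.backward(d[:, : self._split])
        self.tower_mir.backward(d[:, self._split :])

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()] + [
            a.copy()
            for l in self.all_layers()
            if isinstance(l, BatchNorm)
            for a in (l.running_mean, l.running_var)
        ]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        extra = state[len(params) :]
        i = 0
        for l in self.all_layers():
            if isinstance(l, BatchNorm):
                l.running_mean[...] = extra[i]
                l.running_var[...] = extra[i + 1]
                i += 2


def _split_X(X):
    """Accept (n, 2, H, W, C) arrays or (X_lnc, X_mir) tuples."""
    if isinstance(X, (tuple, list)) and len(X) == 2:
        xa, xb = np.asarray(X[0], dtype=F32), np.asarray(X[1], dtype=F32)
    else:
        X = np.asarray(X, dtype=F32)
        if X.ndim != 5 or X.shape[1] != 2:
            raise ValueError(
                f"expected (n, 2, H, W, C) pair tensors or an (X_lnc, X_mir) tuple, got shape {X.shape}"
            )
        xa, xb = X[:, 0], X[:, 1]
    if xa.shape != xb.shape:
        raise ValueError(f"tower input shapes differ: {xa.shape} vs {xb.shape}")
    return xa, xb


class TwinTowerClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style estimator wrapping the twin-tower CNN.

    ``X`` is either an array of shape (n, 2, H, W, C) stacking the lncRNA and
    miRNA tensors, or a tuple ``(X_lnc, X_mir)`` of two (n, H, W, C) arrays.
    ``y`` holds binary labels. Training is deterministic for a fixed ``seed``
    (single-threaded numpy).

    Attributes
    ----------
    net_ : _TwinTowerNet
        The trained network.
    history_ : dict
        Per-epoch "train_loss" and (if a validation split is used) "val_loss".
    classes_ : ndarray
        Always [0, 1].
    """

    def __init__(
        self,
        conv_blocks: tuple[int, ...] = (32, 64),
        kernel: int = 3,
        dropout_rate: float = 0.25,
        dense_units: tuple[int, ...] = (128,),
        dense_dropout: float = 0.5,
        batch_size: int = 64,
        epochs: int = 50,
        learning_rate: float = 1e-3,
        validation_fraction: float = 0.15,
        patience: int = 10,
        input_scaling: str = "log1p",
        seed: int = 0,
    ):
        self.conv_blocks = conv_blocks
        self.kernel = kernel
        self.dropout_rate = dropout_rate
        self.dense_units = dense_units
        self.dense_dropout = dense_dropout
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.input_scaling = input_scaling
        self.seed = seed

    def _config(self) -> ModelConfig:
        return ModelConfig(
            conv_blocks=tuple(self.conv_blocks),
            kernel=self.kernel,
            dropout_rate=self.dropout_rate,
            dense_units=tuple(self.dense_units),
            dense_dropout=self.dense_dropout,
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            validation_fraction=self.validation_fraction,
            patience=self.patience,
            seed=self.seed,
        )

    def _scale(self, x: np.ndarray) -> np.ndarray:
        if self.input_scaling == "log1p":
            return np.log1p(x)
        if self.input_scaling in (None, "none"):
            return x
        raise ValueError(f"unknown input_scaling {self.input_scaling!r}")

    def fit(self, X, y):
        xa, xb = _split_X(X)
        y = np.asarray(y, dtype=F32).ravel()
        if len(y) != len(xa):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = np.array([0, 1])
        xa, xb = self._scale(xa), self._scale(xb)

        rng = np.random.Generator(np.random.PCG64(self.seed))
        n = len(y)
        # stratified validation split for early stopping
        n_val = int(round(self.validation_fraction * n))
        use_val = n_val >= 2 and self.patience > 0
        order = rng.permutation(n)
        if use_val:
            pos = order[y[order] == 1]
            neg = order[y[order] == 0]
            nvp = max(1, int(round(self.validation_fraction * len(pos))))
            nvn = max(1, int(round(self.validation_fraction * len(neg))))
            val_idx = np.concatenate([pos[:nvp], neg[:nvn]])
            tr_idx = np.concatenate([pos[nvp:], neg[nvn:]])
            if len(np.unique(y[tr_idx])) < 2:
                use_val, tr_idx = False, np.arange(n)
        else:
            tr_idx = np.arange(n)

        net = _TwinTowerNet(xa.shape[1:], self._config())
        opt = Adam(net.parameters(), lr=self.learning_rate)
        self.history_ = {"train_loss": [], "val_loss": []}
        best_val, best_state, since_best = np.inf, None, 0

        for _epoch in range(self.epochs):
            perm = tr_idx[rng.permutation(len(tr_idx))]
            losses = []
            for start in range(0, len(perm), self.batch_size):
                b = perm[start : start + self.batch_size]
                if len(b) < 2:
                    continue  # batch norm needs >= 2 samples
                logits = net.forward(xa[b], xb[b], train=True)
                loss, dlogits = bce_loss_and_grad(logits, y[b])
                net.backward(dlogits)
                opt.step(net.gradients())
                losses.append(loss)
            self.history_["train_loss"].append(float(np.mean(losses)))
            if use_val:
                val_logits = net.forward(xa[val_idx], xb[val_idx], train=False)
                val_loss, _ = bce_loss_and_grad(val_logits, y[val_idx])
                self.history_["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val, best_state, since_best = val_loss, net.state(), 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if best_state is not None:
            net.load_state(best_state)
        self.net_ = net
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("TwinTowerClassifier is not fitted")
        xa, xb = _split_X(X)
        if len(xa) == 0:
            return np.zeros((0, 2))
        p = sigmoid(self.net_.forward(self._scale(xa), self._scale(xb), train=False))
        return np.column_stack([1 - p, p]).astype(float)

    def predict(self, X) -> np.ndarray:
        """Binary calls; positive iff probability strictly exceeds 0.5."""
        return (self.predict_proba(X)[:, 1] > DECISION_THRESHOLD).astype(int)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.net_.state())}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self._config())))

    @classmethod
    def load(cls, path: str | Path, in_shape=(20, 20, 4)) -> "TwinTowerClassifier":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        est = cls(
            conv_blocks=tuple(cfg["conv_blocks"]),
            kernel=cfg["kernel"],
            dropout_rate=cfg["dropout_rate"],
            dense_units=tuple(cfg["dense_units"]),
            dense_dropout=cfg["dense_dropout"],
            batch_size=cfg["batch_size"],
            epochs=cfg["epochs"],
            learning_rate=cfg["learning_rate"],
            validation_fraction=cfg["validation_fraction"],
            patience=cfg["patience"],
            seed=cfg["seed"],
        )
        est.classes_ = np.array([0, 1])
        est.net_ = _TwinTowerNet(in_shape, est._config())
        data = np.load(path.with_suffix(".npz"))
        est.net_.load_state([data[f"p{i}"] for i in range(len(data.files))])
        est.history_ = {"train_loss": [], "val_loss": []}
        return est


def build_model(config: ModelConfig, in_shape=(20, 20, 4)) -> _TwinTowerNet:
    """Construct an untrained twin-tower network for the given input shape."""
    return _TwinTowerNet(in_shape, config)


def train(X, y, config: ModelConfig | None = None) -> TwinTowerClassifier:
    """Fit a TwinTowerClassifier on labeled pair tensors."""
    cfg = config or ModelConfig()
    est = TwinTowerClassifier(
        conv_blocks=cfg.conv_blocks,
        kernel=cfg.kernel,
        dropout_rate=cfg.dropout_rate,
        dense_units=cfg.dense_units,
        dense_dropout=cfg.dense_dropout,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        validation_fraction=cfg.validation_fraction,
        patience=cfg.patience,
        seed=cfg.seed,
    )
    return est.fit(X, y)


def predict(model: TwinTowerClassifier, pairs, ids=None) -> list[Prediction]:
    """Score tensor pairs; returns Prediction records (call = p > 0.5)."""
    xa, xb = _split_X(pairs) if not isinstance(pairs, tuple) else pairs
    probs = model.predict_proba((xa, xb))[:, 1] if len(xa) else []
    if ids is None:
        ids = [(f"lnc{i}", f"mir{i}") for i in range(len(xa))]
    return [Prediction(l, m, float(p)) for (l, m), p in zip(ids, probs)]
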