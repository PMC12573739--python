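"""Compact convolutional network for ARP classification (EEGNet-8,2 style).

A small CNN operating on channels x time EEG matrices: a temporal
convolution bank (8 filters), a depthwise spatial convolution across
channels (2 filters per temporal filter), and a separable temporal
convolution block, with batch normalisation, ELU activations, average
pooling and dropout, feeding a 4-way softmax.  Implemented directly on
numpy arrays with explicit backpropagation and an Adam optimizer, so the
same graph also supports reference-based attribution (DeepLIFT-Rescale)
without a deep-learning framework.

Array convention: inputs are ``(batch, channels, time)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------- layers


class Layer:
    """Base layer: forward caches what backward needs; params are dicts."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backprop_input_eval(self, grad: np.ndarray) -> np.ndarray:
        """Input gradient/multiplier through the layer's eval-mode linear map."""
        return self.backward(grad)


def _windows_lastaxis(x: np.ndarray, k: int, pad_left: int, pad_right: int) -> np.ndarray:
    pad = [(0, 0)] * (x.ndim - 1) + [(pad_left, pad_right)]
    xp = np.pad(x, pad)
    return np.lib.stride_tricks.sliding_window_view(xp, k, axis=-1)


class TemporalConv(Layer):
    """Same-padded 1-D convolution along time, shared across EEG channels.

    Input (N, C, T) -> output (N, F, C, T).
    """

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        lim = np.sqrt(6.0 / (kernel + n_filters * kernel))
        self.params["W"] = rng.uniform(-lim, lim, size=(n_filters, kernel))
        self.pad_left = kernel // 2
        self.pad_right = kernel - 1 - self.pad_left

    def forward(self, x, training):
        self._win = _windows_lastaxis(x, self.k, self.pad_left, self.pad_right)
        # (N, C, T, K) @ (K, F) -> (N, C, T, F)
        out = self._win @ self.params["W"].T
        return np.moveaxis(out, -1, 1)

    def backward(self, grad):
        g = np.moveaxis(grad, 1, -1)  # (N, C, T, F)
        self.grads["W"] = np.einsum("nctf,nctk->fk", g, self._win)
        return self.backprop_input_eval(grad)

    def backprop_input_eval(self, grad):
        # full correlation with the flipped kernel
        g = np.moveaxis(grad, 1, -1)  # (N, C, T, F)
        W = self.params["W"]
        gw = _windows_lastaxis(
            np.moveaxis(g, -1, 1), self.k, self.pad_right, self.pad_left
        )  # (N, F, C, T, K)
        return np.einsum("nfctk,fk->nct", gw, W[:, ::-1])


class DepthwiseSpatial(Layer):
    """Per-temporal-filter spatial filters collapsing the channel axis.

    Input (N, F, C, T) -> output (N, F*D, T).
    """

    def __init__(self, n_filters: int, depth: int, n_channels: int, rng: np.random.Generator):
        super().__init__()
        self.F, self.D, self.C = n_filters, depth, n_channels
        lim = np.sqrt(6.0 / (n_channels + depth))
        self.params["W"] = rng.uniform(-lim, lim, size=(n_filters, depth, n_channels))

    def forward(self, x, training):
        self._x = x
        out = np.einsum("nfct,fdc->nfdt", x, self.params["W"])
        return out.reshape(x.shape[0], self.F * self.D, x.shape[-1])

    def backward(self, grad):
        g = grad.reshape(grad.shape[0], self.F, self.D, grad.shape[-1])
        self.grads["W"] = np.einsum("nfdt,nfct->fdc", g, self._x)
        return self.backprop_input_eval(grad)

    def backprop_input_eval(self, grad):
        g = grad.reshape(grad.shape[0], self.F, self.D, grad.shape[-1])
        return np.einsum("nfdt,fdc->nfct", g, self.params["W"])


class DepthwiseTemporal(Layer):
    """Per-feature-map same-padded 1-D convolution along time (N, F, T)."""

    def __init__(self, n_features: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        lim = np.sqrt(6.0 / (2 * kernel))
        self.params["W"] = rng.uniform(-lim, lim, size=(n_features, kernel))
        self.pad_left = kernel // 2
        self.pad_right = kernel - 1 - self.pad_left

    def forward(self, x, training):
        self._win = _windows_lastaxis(x, self.k, self.pad_left, self.pad_right)
        return np.einsum("nftk,fk->nft", self._win, self.params["W"])

    def backward(self, grad):
        self.grads["W"] = np.einsum("nft,nftk->fk", grad, self._win)
        return self.backprop_input_eval(grad)

    def backprop_input_eval(self, grad):
        gw = _windows_lastaxis(grad, self.k, self.pad_right, self.pad_left)
        return np.einsum("nftk,fk->nft", gw, self.params["W"][:, ::-1])


class PointwiseConv(Layer):
    """1x1 convolution mixing feature maps: (N, F_in, T) -> (N, F_out, T)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.params["W"] = rng.uniform(-lim, lim, size=(n_out, n_in))

    def forward(self, x, training):
        self._x = x
        return np.einsum("nft,gf->ngt", x, self.params["W"])

    def backward(self, grad):
        self.grads["W"] = np.einsum("ngt,nft->gf", grad, self._x)
        return self.backprop_input_eval(grad)

    def backprop_input_eval(self, grad):
        return np.einsum("ngt,gf->nft", grad, self.params["W"])


class BatchNorm(Layer):
    """Feature-map batch normalisation (axis 1), with running eval stats."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.run_mean = np.zeros(n_features)
        self.run_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _bshape(self, x):
        shape = [1] * x.ndim
        shape[1] = x.shape[1]
        return shape

    def forward(self, x, training):
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = self._bshape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
            self._axes, self._m = axes, np.prod([x.shape[i] for i in axes])
            self._xhat = (x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + self.eps)
            self._std = np.sqrt(var + self.eps)
            xhat = self._xhat
        else:
            xhat = (x - self.run_mean.reshape(shape)) / np.sqrt(
                self.run_var.reshape(shape) + self.eps
            )
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)

    def backward(self, grad):
        shape = self._bshape(grad)
        axes, m = self._axes, self._m
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self.params["gamma"].reshape(shape)
        term = (
            g
            - g.mean(axis=axes, keepdims=True)
            - self._xhat * (g * self._xhat).mean(axis=axes, keepdims=True)
        )
        return term / self._std.reshape(shape)

    def backprop_input_eval(self, grad):
        shape = self._bshape(grad)
        scale = self.params["gamma"] / np.sqrt(self.run_var + self.eps)
        return grad * scale.reshape(shape)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def f(self, x):
        return np.where(x > 0, x, self.alpha * (np.expm1(np.minimum(x, 0))))

    def forward(self, x, training):
        self._x = x
        self._y = self.f(x)
        return self._y

    def backward(self, grad):
        return grad * np.where(self._x > 0, 1.0, self._y + self.alpha)

    def backprop_input_eval(self, grad):
        return self.backward(grad)


class AvgPool(Layer):
    """Non-overlapping mean pooling along time; trailing remainder dropped."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x, training):
        t = (x.shape[-1] // self.size) * self.size
        self._t_in = x.shape[-1]
        xr = x[..., :t].reshape(*x.shape[:-1], t // self.size, self.size)
        return xr.mean(axis=-1)

    def backward(self, grad):
        g = np.repeat(grad, self.size, axis=-1) / self.size
        if g.shape[-1] < self._t_in:
            pad = [(0, 0)] * (g.ndim - 1) + [(0, self._t_in - g.shape[-1])]
            g = np.pad(g, pad)
        return g

    def backprop_input_eval(self, grad):
        return self.backward(grad)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def backprop_input_eval(self, grad):
        return grad


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def backprop_input_eval(self, grad):
        return self.backward(grad)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.params["W"] = rng.uniform(-lim, lim, size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return self.backprop_input_eval(grad)

    def backprop_input_eval(self, grad):
        return grad @ self.params["W"].T


# ---------------------------------------------------------------- model


@dataclass
class CompactCNNConfig:
    """Architecture hyperparameters of the EEGNet-8,2-style classifier."""

    n_temporal_filters: int = 8
    spatial_depth: int = 2
    temporal_kernel: int = 64
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.5


class CompactCNN:
    """EEGNet-8,2-style classifier on (channels x time) inputs."""

    def __init__(
        self,
        n_channels: int,
        n_samples: int,
        n_classes: int = 4,
        config: CompactCNNConfig | None = None,
        seed: int | np.random.SeedSequence = 0,
    ):
        cfg = config or CompactCNNConfig()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.n_classes = n_classes
        F1, D = cfg.n_temporal_filters, cfg.spatial_depth
        F2 = F1 * D
        k1 = min(cfg.temporal_kernel, n_samples)
        t1 = n_samples // cfg.pool1
        k2 = min(cfg.separable_kernel, max(1, t1))
        t2 = max(1, t1 // cfg.pool2)
        self.layers: list[Layer] = [
            TemporalConv(F1, k1, rng),
            BatchNorm(F1),
            DepthwiseSpatial(F1, D, n_channels, rng),
            BatchNorm(F2),
            ELU(),
            AvgPool(cfg.pool1),
            Dropout(cfg.dropout, rng),
            DepthwiseTemporal(F2, k2, rng),
            PointwiseConv(F2, F2, rng),
            BatchNorm(F2),
            ELU(),
            AvgPool(cfg.pool2),
            Dropout(cfg.dropout, rng),
            Flatten(),
            Dense(F2 * t2, n_classes, rng),
        ]

    # -- inference ----------------------------------------------------

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        return softmax(self.logits(x, training=False))

    # -- training ------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        for layer in self.layers:
            for name, value in layer.params.items():
                yield layer, name, value

    def n_parameters(self) -> int:
        return sum(v.size for _, _, v in self.parameters())

    def get_weights(self) -> list:
        state = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm):
                entry["_rm"] = layer.run_mean.copy()
                entry["_rv"] = layer.run_var.copy()
            state.append(entry)
        return state

    def set_weights(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for k in layer.params:
                layer.params[k][...] = entry[k]
            if isinstance(layer, BatchNorm):
                layer.run_mean[...] = entry["_rm"]
                layer.run_var[...] = entry["_rv"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


class Adam:
    def __init__(self, model: CompactCNN, lr: float = 1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in model.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in model.layers
        ]

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.model.layers):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1**self.t)
                vhat = self.v[i][k] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainConfig:
    """Optimisation protocol for the ARP classifier.

    Defaults mirror the full protocol (cross-entropy, Adam at 1e-4 with a
    0.7 step decay every 100 epochs, batch size 4, ~25 % of input channels
    zeroed per batch).  ``patience`` > 0 stops early when the validation
    loss has not improved for that many epochs; the returned model is always
    the one with minimal validation loss.
    """

    max_epochs: int = 300
    lr: float = 1e-4
    lr_decay: float = 0.7
    lr_step: int = 100
    batch_size: int = 4
    channel_dropout_frac: float = 0.25
    patience: int | None = None


def reduced_protocol() -> TrainConfig:
    """Shortened schedule for simulation studies: <= 50 epochs at lr 1e-3."""
    return TrainConfig(max_epochs=50, lr=1e-3, patience=10)


def train_compact_cnn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_classes: int = 4,
    config: TrainConfig | None = None,
    arch: CompactCNNConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[CompactCNN, dict]:
    """Train a fresh classifier, returning the minimum-validation-loss model."""
    cfg = config or TrainConfig()
    rng = np.random.default_rng(seed)
    model = CompactCNN(
        X_train.shape[1], X_train.shape[2], n_classes, config=arch, seed=rng.integers(2**31)
    )
    opt = Adam(model, lr=cfg.lr)
    n = len(X_train)
    n_drop = int(round(cfg.channel_dropout_frac * X_train.shape[1]))
    best = {"loss": np.inf, "weights": model.get_weights(), "epoch": -1}
    history = []
    since_best = 0
    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.lr_step)
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = X_train[idx].copy()
            if n_drop > 0:
                drop = rng.choice(X_train.shape[1], n_drop, replace=False)
                xb[:, drop, :] = 0.0
            logits = model.logits(xb, training=True)
            probs = softmax(logits)
            onehot = np.eye(n_classes)[y_train[idx]]
            model.backward((probs - onehot) / len(idx))
            opt.step()
        val_loss = cross_entropy(model.predict_proba(X_val), y_val)
        history.append(val_loss)
        if val_loss < best["loss"] - 1e-9:
            best = {"loss": val_loss, "weights": model.get_weights(), "epoch": epoch}
            since_best = 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best >= cfg.patience:
                break
    model.set_weights(best["weights"])
    return model, {"val_history": history, "best_epoch": best["epoch"], "best_loss": best["loss"]}


def build_compact_cnn(
    n_channels: int,
    n_samples: int,
    n_classes: int = 4,
    config: CompactCNNConfig | None = None,
    seed: int = 0,
) -> CompactCNN:
    """Construct an untrained classifier for the given input geometry."""
    if n_channels < 1 or n_samples < 1 or n_classes < 2:
        raise ValueError("dimensions must be positive (and n_classes >= 2)")
    return CompactCNN(n_channels, n_samples, n_classes, config=config, seed=seed)
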