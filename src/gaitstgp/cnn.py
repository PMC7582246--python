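"""1-D convolutional regression network and per-parameter ensemble.

A compact CNN maps one fixed-length (212-sample) multichannel stride window
to one scalar gait parameter: two valid convolutions each followed by ReLU
and max-pooling, then a flattening layer and two fully-connected layers with
a linear scalar output (a rectified output cannot represent the signed
residual structure of regression targets).  Training minimizes the mean
squared error

    MSE = sum_i (yhat_i - y_i)^2 / n

with the Adam adaptive-moment optimizer (learning rate 0.001, beta1 0.9,
beta2 0.999).  Targets are standardized internally during optimisation and
predictions are returned in label units; reported losses are always in label
units.  The weights reported after training are those of the epoch with the
best validation loss.

The implementation is self-contained numpy: convolution is evaluated as a
batched matrix product over an im2col expansion, and gradients are derived
analytically layer by layer.  An ensemble is one independently trained
network per target parameter for a given sensor combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .params import STGP_NAMES


def mse(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean squared error between prediction and label vectors."""
    p = np.asarray(pred, dtype=float).ravel()
    y = np.asarray(label, dtype=float).ravel()
    if len(p) != len(y) or len(p) == 0:
        raise ValueError("pred and label must have equal nonzero length")
    return float(np.mean((p - y) ** 2))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters: conv-pool-conv-pool-flatten-dense-dense(1)."""

    channels_in: int
    f1: int = 32
    k1: int = 15
    p1: int = 2
    f2: int = 64
    k2: int = 9
    p2: int = 2
    d1: int = 64
    input_length: int = 212

    def __post_init__(self) -> None:
        for name in ("channels_in", "f1", "k1", "p1", "f2", "k2", "p2", "d1", "input_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flat_length() < 1:
            raise ValueError("receptive field exceeds the input length")

    def conv1_out(self) -> int:
        return self.input_length - self.k1 + 1

    def pool1_out(self) -> int:
        return self.conv1_out() // self.p1

    def conv2_out(self) -> int:
        return self.pool1_out() - self.k2 + 1

    def pool2_out(self) -> int:
        return self.conv2_out() // self.p2

    def flat_length(self) -> int:
        return self.pool2_out() * self.f2

    def parameter_count(self) -> int:
        """Total trainable parameters (closed form)."""
        return (
            self.f1 * (self.channels_in * self.k1 + 1)
            + self.f2 * (self.f1 * self.k2 + 1)
            + self.d1 * (self.flat_length() + 1)
            + (self.d1 + 1)
        )


@dataclass(frozen=True)
class TrainingConfig:
    loss: str = "mse"
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "mse":
            raise ValueError("only the mse loss is supported")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (n, c, L) -> (n, L-k+1, c*k)
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (n, c, Lo, k)
    return win.transpose(0, 2, 1, 3).reshape(x.shape[0], x.shape[2] - k + 1, -1)


class _Conv1D:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.normal(0.0, scale, (c_out, c_in * k))).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _im2col(x, self.k)          # (n, Lo, c_in*k)
        self._in_len = x.shape[2]
        out = self._cols @ self.W.T + self.b      # (n, Lo, c_out)
        return out.transpose(0, 2, 1)             # (n, c_out, Lo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout.transpose(0, 2, 1)               # (n, Lo, c_out)
        n, lo, _ = d.shape
        self.dW = d.reshape(-1, d.shape[2]).T @ self._cols.reshape(-1, self._cols.shape[2])
        self.db = d.sum(axis=(0, 1))
        dcols = d @ self.W                        # (n, Lo, c_in*k)
        dcols = dcols.reshape(n, lo, self.c_in, self.k)
        dx = np.zeros((n, self.c_in, self._in_len), dtype=np.float32)
        for j in range(self.k):
            dx[:, :, j:j + lo] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _MaxPool:
    def __init__(self, size: int):
        self.size = size

    def forward(self, x):
        n, c, L = x.shape
        lo = L // self.size
        xr = x[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout):
        n, c, lo = dout.shape
        dx = np.zeros(self._shape, dtype=np.float32)
        dxr = dx[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        idx_n, idx_c, idx_l = np.ogrid[:n, :c, :lo]
        dxr[idx_n, idx_c, idx_l, self._arg] = dout
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class CNNRegressor:
    """The two-convolution regression network."""

    def __init__(self, spec: NetworkSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.seed = seed
        self.layers = [
            _Conv1D(spec.channels_in, spec.f1, spec.k1, rng),
            _ReLU(),
            _MaxPool(spec.p1),
            _Conv1D(spec.f1, spec.f2, spec.k2, rng),
            _ReLU(),
            _MaxPool(spec.p2),
            _Flatten(),
            _Dense(spec.flat_length(), spec.d1, rng),
            _ReLU(),
            _Dense(spec.d1, 1, rng),
        ]
        # target standardization, fitted during training
        self.y_mean = 0.0
        self.y_scale = 1.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=np.float32)
        if h.shape[1] != self.spec.channels_in:
            raise ValueError(
                f"expected {self.spec.channels_in} channels, got {h.shape[1]}"
            )
        for layer in self.layers:
            h = layer.forward(h)
        return h[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        d = dout[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i:i + batch_size]))
        return np.concatenate(out) * self.y_scale + self.y_mean if out else np.empty(0)

    def parameter_count(self) -> int:
        return int(sum(p.size for l in self.layers for (_, p, _) in l.params()))

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for l in self.layers for (_, p, _) in l.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for l in self.layers:
            for (name, p, _) in l.params():
                p[...] = next(it)


def build_network(spec: NetworkSpec, seed: int) -> CNNRegressor:
    """Deterministically initialized network for the given architecture."""
    return CNNRegressor(spec, seed)


class _Adam:
    def __init__(self, model: CNNRegressor, config: TrainingConfig):
        self.cfg = config
        self.m = [np.zeros_like(p) for l in model.layers for (_, p, _) in l.params()]
        self.v = [np.zeros_like(p) for l in model.layers for (_, p, _) in l.params()]
        self.t = 0

    def step(self, model: CNNRegressor) -> None:
        self.t += 1
        c = self.cfg
        i = 0
        for layer in model.layers:
            for (name, p, gname) in layer.params():
                g = getattr(layer, gname).astype(np.float32)
                self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * g
                self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * g * g
                mhat = self.m[i] / (1 - c.beta1 ** self.t)
                vhat = self.v[i] / (1 - c.beta2 ** self.t)
                p -= c.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
                i += 1


def train(
    model: CNNRegressor,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainingConfig,
) -> Tuple[CNNRegressor, List[Dict[str, float]]]:
    """Minimize MSE with Adam; keep the best-validation-epoch weights.

    Returns the trained model and a history of per-epoch train/validation
    losses (label units).
    """
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    ty = np.asarray(train_y, dtype=float)
    model.y_mean = float(np.mean(ty))
    model.y_scale = float(np.std(ty)) or 1.0
    ty_s = ((ty - model.y_mean) / model.y_scale).astype(np.float32)

    opt = _Adam(model, config)
    history: List[Dict[str, float]] = []
    best_val = np.inf
    best_weights = model.get_weights()
    n = len(train_x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        train_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = train_x[idx], ty_s[idx]
            pred = model.forward(xb)
            resid = pred - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // config.batch_size}"
                )
            model.backward(2.0 * resid / len(idx))
            opt.step(model)
            train_losses.append(loss)
        val_pred = model.predict(val_x)
        val_mse = mse(val_pred, val_y)
        history.append(
            {
                "epoch": epoch,
                "train_mse": float(np.mean(train_losses)) * model.y_scale ** 2,
                "val_mse": val_mse,
            }
        )
        if val_mse < best_val:
            best_val = val_mse
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return model, history


@dataclass
class EnsembleModel:
    """One trained network per target STGP for one sensor combination."""

    combination: str
    networks: Dict[str, CNNRegressor] = field(default_factory=dict)
    history: Dict[str, List[Dict[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        chans = {net.spec.channels_in for net in self.networks.values()}
        if len(chans) > 1:
            raise ValueError("ensemble members disagree on input channels")


def train_ensemble(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    val_x: np.ndarray,
    val_labels: np.ndarray,
    combination: str,
    targets: Sequence[str],
    config: TrainingConfig,
    spec: Optional[NetworkSpec] = None,
) -> EnsembleModel:
    """Train one network per target on channel-sliced segment arrays.

    ``train_labels`` / ``val_labels`` are (n, 12) arrays in STGP_NAMES order.
    """
    for t in targets:
        if t not in STGP_NAMES:
            raise ValueError(f"unknown target {t!r}")
    spec = spec or NetworkSpec(channels_in=train_x.shape[1])
    ens = EnsembleModel(combination=combination)
    for t in targets:
        col = STGP_NAMES.index(t)
        net = build_network(spec, seed=config.seed)
        net, hist = train(
            net, train_x, train_labels[:, col], val_x, val_labels[:, col], config
        )
        ens.networks[t] = net
        ens.history[t] = hist
    return ens


def predict(ensemble: EnsembleModel, segments: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-target predictions (label units) for an array of segments."""
    out = {}
    for t, net in ensemble.networks.items():
        if len(segments) and segments.shape[1] != net.spec.channels_in:
            raise ValueError(
                f"segments have {segments.shape[1]} channels; "
                f"network expects {net.spec.channels_in}"
            )
        out[t] = net.predict(segments) if len(segments) else np.empty(0)
    return out
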