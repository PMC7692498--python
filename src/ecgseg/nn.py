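"""Minimal NumPy implementation of the 1D convolutional beat classifier.

Architecture (for the default spec and input length 300):

    conv(k=49) -> relu -> maxpool(2)   : 300 -> 252 -> 126
    conv(k=25) -> relu -> maxpool(2)   : 126 -> 102 ->  51
    conv(k=9)  -> relu -> maxpool(2)   :  51 ->  43 ->  21
    conv(k=9)  -> relu -> maxpool(2)   :  21 ->  13 ->   6
    flatten -> dense -> relu -> dense -> relu -> dropout -> dense(2) -> softmax

All convolutions use stride 1 and no padding; pooling is max with width
and stride 2 (a trailing odd sample is dropped).  Training is plain SGD
with momentum under a piecewise-constant learning-rate schedule, with
softmax cross-entropy loss.  Everything is float32 and driven by a single
seeded NumPy generator, so runs are bit-reproducible.

Convolutions are evaluated as im2col matrix products (BLAS-backed), which
keeps CPU training of the default model tractable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["ModelSpec", "TrainConfig", "CNNModel", "build_model",
           "conv_output_lengths", "lr_for_epoch", "save_model", "load_model"]

_FORMAT_VERSION = "ecgseg-cnn-1"


@dataclass(frozen=True)
class ModelSpec:
    """Hyper-structure of the network.

    Kernel widths, the pool width/stride of 2 and the zero padding are
    fixed design constants; channel counts and dense widths are not fixed
    by the published design and stay configurable, with defaults sized to
    train on a CPU in minutes.
    """

    input_len: int = 300
    kernel_widths: tuple[int, ...] = (49, 25, 9, 9)
    channels: tuple[int, ...] = (32, 32, 64, 64)
    dense_widths: tuple[int, ...] = (512, 128)
    dropout: float = 0.5
    n_classes: int = 2
    zscore_input: bool = False

    def __post_init__(self) -> None:
        if len(self.kernel_widths) != len(self.channels):
            raise ValueError("kernel_widths and channels must have equal length")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule.

    The published schedule: 30 epochs of SGD with momentum 0.9 and
    cross-entropy loss, learning rate 0.01 for epochs 1-3, 0.005 for
    epochs 4-10, 0.001 for 11-20 and 0.0001 for 21-30; 30 % of the
    samples are held out (stratified within each record) for validation.
    """

    epochs: int = 30
    lr_schedule: tuple[tuple[int, float], ...] = (
        (3, 0.01), (7, 0.005), (10, 0.001), (10, 0.0001))
    momentum: float = 0.9
    batch_size: int = 256
    val_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")


def lr_for_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a 1-based epoch number under the schedule."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    upto = 0
    for n, lr in cfg.lr_schedule:
        upto += n
        if epoch <= upto:
            return lr
    return cfg.lr_schedule[-1][1]


def conv_output_lengths(input_len: int, kernel_widths: tuple[int, ...]) -> list[tuple[int, int]]:
    """Per-stage (after-conv, after-pool) temporal lengths.

    Raises with the offending stage named if the length collapses.
    """
    lengths = []
    L = input_len
    for i, k in enumerate(kernel_widths, start=1):
        Lc = L - k + 1
        if Lc < 1:
            raise ValueError(
                f"input length collapses at conv stage {i}: length {L} < kernel {k}"
            )
        Lp = Lc // 2
        if Lp < 1:
            raise ValueError(f"input length collapses at pool stage {i}")
        lengths.append((Lc, Lp))
        L = Lp
    return lengths


# ---------------------------------------------------------------------------
# layers (forward + backward), float32 throughout
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, c, L) -> (n, L-k+1, c*k) sliding windows, contiguous."""
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (n, c, Lout, k)
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
        x.shape[0], x.shape[2] - k + 1, x.shape[1] * k)


class _Conv1D:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((c_out, c_in, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)  # (n, Lout, c_in*k)
        n, Lout, _ = self._cols.shape
        W2 = self.W.reshape(self.W.shape[0], -1)  # (c_out, c_in*k)
        out = self._cols.reshape(n * Lout, -1) @ W2.T + self.b
        return out.reshape(n, Lout, -1).transpose(0, 2, 1)  # (n, c_out, Lout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c_out, Lout = dy.shape
        dy_flat = dy.transpose(0, 2, 1).reshape(n * Lout, c_out)
        cols_flat = self._cols.reshape(n * Lout, -1)
        self.dW = (dy_flat.T @ cols_flat).reshape(self.W.shape)
        self.db = dy_flat.sum(axis=0)
        # full correlation of dy with flipped kernels gives dx
        k = self.k
        pad = np.zeros((n, c_out, Lout + 2 * (k - 1)), dtype=dy.dtype)
        pad[:, :, k - 1: k - 1 + Lout] = dy
        cols = _im2col(pad, k)  # (n, L_in, c_out*k)
        Wf = self.W[:, :, ::-1].transpose(1, 0, 2).reshape(self.W.shape[1], -1)  # (c_in, c_out*k)
        dx = cols.reshape(n * (Lout + k - 1), -1) @ Wf.T
        return dx.reshape(n, Lout + k - 1, -1).transpose(0, 2, 1)

    def params(self):
        return [("W", self), ("b", self)]


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        Lp = L // 2
        self._L = L
        xt = x[:, :, : 2 * Lp].reshape(n, c, Lp, 2)
        self._arg = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, Lp = dy.shape
        dx = np.zeros((n, c, Lp, 2), dtype=dy.dtype)
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        dx = dx.reshape(n, c, 2 * Lp)
        if self._L != 2 * Lp:
            dx = np.concatenate(
                [dx, np.zeros((n, c, self._L - 2 * Lp), dtype=dy.dtype)], axis=2)
        return dx


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class CNNModel:
    """The network with explicit forward/backward passes.

    Use :func:`build_model` to construct one; :meth:`predict_proba` is
    the inference entry point, :meth:`train_batch` one SGD step.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.stage_lengths = conv_output_lengths(spec.input_len, spec.kernel_widths)

        self.convs: list[_Conv1D] = []
        c_in = 1
        for k, c_out in zip(spec.kernel_widths, spec.channels):
            self.convs.append(_Conv1D(c_in, c_out, k, rng))
            c_in = c_out
        self.flat_dim = spec.channels[-1] * self.stage_lengths[-1][1]

        self.denses: list[_Dense] = []
        n_in = self.flat_dim
        for w in spec.dense_widths:
            self.denses.append(_Dense(n_in, w, rng))
            n_in = w
        self.head = _Dense(n_in, spec.n_classes, rng)

        self._relu_c = [_ReLU() for _ in self.convs]
        self._pools = [_MaxPool2() for _ in self.convs]
        self._relu_d = [_ReLU() for _ in self.denses]
        self._velocity: dict[int, np.ndarray] = {}

    # -- parameter bookkeeping -------------------------------------------

    def _layers_with_params(self):
        return [*self.convs, *self.denses, self.head]

    def n_parameters(self) -> int:
        return sum(l.W.size + l.b.size for l in self._layers_with_params())

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self._layers_with_params()):
            out[f"W{i}"] = l.W
            out[f"b{i}"] = l.b
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self._layers_with_params()):
            l.W = weights[f"W{i}"].astype(np.float32)
            l.b = weights[f"b{i}"].astype(np.float32)

    # -- passes -----------------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec.input_len:
            raise ValueError(
                f"expected input length {self.spec.input_len}, got {X.shape[1]}")
        if self.spec.zscore_input:
            mu = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, keepdims=True)
            X = (X - mu) / np.maximum(sd, 1e-8)
        return X[:, None, :]  # (n, 1, L)

    def _forward(self, X: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> np.ndarray:
        h = X
        for conv, relu, pool in zip(self.convs, self._relu_c, self._pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        h = h.reshape(h.shape[0], -1)
        for dense, relu in zip(self.denses, self._relu_d):
            h = relu.forward(dense.forward(h))
        if train and self.spec.dropout > 0:
            keep = 1.0 - self.spec.dropout
            self._drop_mask = (rng.random(h.shape) < keep).astype(np.float32) / keep
            h = h * self._drop_mask
        else:
            self._drop_mask = None
        logits = self.head.forward(h)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, shape (n, n_classes)."""
        return self._forward(self._prepare(X), train=False, rng=None)

    def train_batch(self, X: np.ndarray, y: np.ndarray, lr: float,
                    momentum: float, rng: np.random.Generator) -> float:
        """One SGD-with-momentum step on a mini-batch; returns mean loss."""
        Xp = self._prepare(X)
        n = Xp.shape[0]
        probs = self._forward(Xp, train=True, rng=rng)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: loss={loss} (lr={lr}); inspect input scaling")

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dh = self.head.backward(dlogits.astype(np.float32))
        if self._drop_mask is not None:
            dh = dh * self._drop_mask
        for dense, relu in zip(reversed(self.denses), reversed(self._relu_d)):
            dh = dense.backward(relu.backward(dh))
        dh = dh.reshape(-1, self.spec.channels[-1], self.stage_lengths[-1][1])
        for conv, relu, pool in zip(reversed(self.convs), reversed(self._relu_c),
                                    reversed(self._pools)):
            dh = conv.backward(relu.backward(pool.backward(dh)))

        for l in self._layers_with_params():
            for name in ("W", "b"):
                p = getattr(l, name)
                g = getattr(l, "d" + name)
                key = id(l) * 2 + (name == "b")
                v = self._velocity.get(key)
                if v is None:
                    v = np.zeros_like(p)
                v = momentum * v - lr * g
                p += v
                self._velocity[key] = v
        return loss


def build_model(spec: ModelSpec = ModelSpec(), seed: int = 0) -> CNNModel:
    """Construct a freshly initialised network for the given spec."""
    return CNNModel(spec, seed=seed)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: CNNModel, path: str | Path) -> Path:
    """Serialise weights + spec to a single ``.npz`` artifact."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"format": _FORMAT_VERSION, "spec": asdict(model.spec)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.get_weights())
    return path


def load_model(path: str | Path) -> CNNModel:
    """Load a model saved by :func:`save_model`; round-trips predictions exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model artifact not found: {path}")
    with np.load(path) as data:
        if "__meta__" not in data:
            raise ValueError(f"{path} is not a model artifact: missing '__meta__'")
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != _FORMAT_VERSION:
            raise ValueError(
                f"model format mismatch in field 'format': expected "
                f"{_FORMAT_VERSION!r}, found {meta.get('format')!r}")
        spec_d = meta["spec"]
        for key in ("kernel_widths", "channels", "dense_widths"):
            spec_d[key] = tuple(spec_d[key])
        spec = ModelSpec(**spec_d)
        model = CNNModel(spec, seed=0)
        model.set_weights({k: data[k] for k in data.files if k != "__meta__"})
    return model
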