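"""A small seeded feed-forward network engine (numpy).

Implements exactly what the two classifiers need: 1-D convolution ("same"
padding), max-pooling, fully connected layers, ReLU, a softmax +
categorical-cross-entropy head, Glorot-uniform initialization, and the Adam
optimizer.  All randomness flows through an explicit ``numpy`` Generator, so
two networks built from the same seed have identical initial parameters and
identical training trajectories.

Layers store their forward activations, so ``backward`` must follow a
``forward(..., train=True)`` on the same batch.  float32 is the default
compute dtype; tests use float64 for numeric gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "SequentialNet",
    "Adam",
    "glorot_uniform",
    "TrainingDivergenceError",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype=np.float32) -> np.ndarray:
    """Uniform(-l, l) with l = sqrt(6 / (fan_in + fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _relu_backward(grad: np.ndarray, activated: np.ndarray) -> np.ndarray:
    return grad * (activated > 0)


class Conv1D:
    """1-D convolution with 'same' zero padding, optional ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 activation: str = "relu", dtype=np.float32) -> None:
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.activation = activation
        fan_in = kernel * in_ch
        fan_out = kernel * out_ch
        self.W = glorot_uniform(rng, fan_in, fan_out, (in_ch * kernel, out_ch), dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # x: (N, L, C)
        n, length, _ = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # win: (N, L, C, kernel) -> columns (N*L, C*kernel)
        col = win.reshape(n * length, self.in_ch * self.kernel)
        y = (col @ self.W + self.b).reshape(n, length, self.out_ch)
        if self.activation == "relu":
            np.maximum(y, 0.0, out=y)
        if train:
            self._col = col
            self._out = y
            self._in_shape = x.shape
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, length, _ = self._in_shape
        pad = self.kernel // 2
        if self.activation == "relu":
            grad = _relu_backward(grad, self._out)
        g = grad.reshape(n * length, self.out_ch)
        self.dW[...] = self._col.T @ g
        self.db[...] = g.sum(axis=0)
        dcol = (g @ self.W.T).reshape(n, length, self.in_ch, self.kernel)
        dxp = np.zeros((n, length + 2 * pad, self.in_ch), dtype=grad.dtype)
        for k in range(self.kernel):
            dxp[:, k : k + length, :] += dcol[:, :, :, k]
        return dxp[:, pad : pad + length, :]


class MaxPool1D:
    """Non-overlapping max pooling along the length axis."""

    def __init__(self, pool: int = 2) -> None:
        self.pool = pool
        self.params: list = []
        self.grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, c = x.shape
        if length % self.pool:
            raise ValueError(
                f"length {length} not divisible by pool size {self.pool}"
            )
        xr = x.reshape(n, length // self.pool, self.pool, c)
        idx = xr.argmax(axis=2)
        y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, length, c = self._in_shape
        dxr = np.zeros((n, length // self.pool, self.pool, c), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :], grad[:, :, None, :], axis=2)
        return dxr.reshape(n, length, c)


class Flatten:
    def __init__(self) -> None:
        self.params: list = []
        self.grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Dense:
    """Fully connected layer; activation in {'relu', 'linear'}.

    The softmax of the output layer lives in the loss head
    (:meth:`SequentialNet.loss_and_grad`), the usual fused formulation.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "relu", dtype=np.float32) -> None:
        self.activation = activation
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out), dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = x @ self.W + self.b
        if self.activation == "relu":
            np.maximum(y, 0.0, out=y)
        if train:
            self._in = x
            self._out = y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            grad = _relu_backward(grad, self._out)
        self.dW[...] = self._in.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SequentialNet:
    """An ordered stack of layers with a softmax cross-entropy head."""

    def __init__(self, layers) -> None:
        self.layers = list(layers)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.vstack(out) if out else np.zeros((0, 0))

    def loss_and_grad(self, logits: np.ndarray, y_onehot: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean categorical cross-entropy and its gradient w.r.t. logits."""
        probs = softmax(logits)
        n = logits.shape[0]
        loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
        return float(loss), (probs - y_onehot) / n

    def fit(
        self,
        x: np.ndarray,
        y_onehot: np.ndarray,
        epochs: int,
        batch_size: int,
        rng: np.random.Generator,
        lr: float = 1e-3,
    ) -> list[dict]:
        """Mini-batch Adam training; returns per-epoch history records."""
        opt = Adam(self.params, lr=lr)
        n = x.shape[0]
        history = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            correct = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.forward(x[idx], train=True)
                loss, dlogits = self.loss_and_grad(logits, y_onehot[idx])
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(epoch)
                self.backward(dlogits.astype(logits.dtype))
                opt.step(self.grads)
                losses.append(loss * len(idx))
                correct += int(
                    (logits.argmax(axis=1) == y_onehot[idx].argmax(axis=1)).sum()
                )
            history.append(
                {"epoch": epoch, "loss": sum(losses) / n, "accuracy": correct / n}
            )
        return history
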