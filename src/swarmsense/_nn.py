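"""Minimal NumPy CNN: layers, softmax cross-entropy, and Adam.

Float32 throughout; convolutions are valid (no padding), stride 1,
implemented as im2col + BLAS matmul.  Channel-last layout (N, H, W, C).
Only what the four-class trajectory-image classifier needs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Dense",
    "softmax",
    "SoftmaxCrossEntropy",
    "Adam",
    "Sequential",
]


class Conv2D:
    """Valid 2-D convolution, stride 1, kernel (k, k, c_in, c_out)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * c_in))  # He initialization
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # (N, OH, OW, C, k, k) -> (N*OH*OW, k*k*C) matching W.reshape(k*k*C, -1)
        cols = np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3))
        cols = cols.reshape(n * oh * ow, k * k * c)
        out = cols @ self.W.reshape(-1, self.W.shape[-1]) + self.b
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, oh, ow, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        dflat = dout.reshape(n * oh * ow, -1)
        self.dW[:] = (self._cols.T @ dflat).reshape(self.W.shape)
        self.db[:] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(-1, self.W.shape[-1]).T).reshape(
            n, oh, ow, k, k, c
        )
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        for i in range(k):  # col2im scatter-add
            for j in range(k):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dx


class ReLU:
    """Rectifier f(i) = max(0, i)."""

    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def __init__(self):
        self._x: np.ndarray | None = None
        self._out: np.ndarray | None = None

    def params(self):
        return []

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        return x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self._windows(x).max(axis=(2, 4))
        if train:
            self._x = x
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win = self._windows(self._x)
        is_max = win == self._out[:, :, None, :, None, :]
        counts = is_max.sum(axis=(2, 4), keepdims=True)  # split gradient on ties
        grad = is_max * (dout[:, :, None, :, None, :] / counts)
        n, h, w, c = self._x.shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros_like(self._x)
        dx[:, : 2 * h2, : 2 * w2, :] = grad.reshape(n, 2 * h2, 2 * w2, c)
        self._x = self._out = None
        return dx


class Flatten:
    def __init__(self):
        self._shape: tuple | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense:
    """Fully connected layer, weights (d_in, d_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SoftmaxCrossEntropy:
    """Combined softmax + categorical cross-entropy (mean over the batch)."""

    def __init__(self):
        self._probs: np.ndarray | None = None
        self._labels: np.ndarray | None = None

    def loss(self, logits: np.ndarray, labels: np.ndarray) -> float:
        probs = softmax(logits.astype(np.float64))
        self._probs = probs
        self._labels = labels
        picked = probs[np.arange(len(labels)), labels]
        return float(-np.log(np.maximum(picked, 1e-12)).mean())

    def backward(self) -> np.ndarray:
        n = len(self._labels)
        grad = self._probs.copy()
        grad[np.arange(n), self._labels] -= 1.0
        return (grad / n).astype(np.float32)


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in params]
            self._v = [np.zeros_like(p) for p, _ in params]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(params, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """A plain layer stack trained with mini-batch SGD via Adam."""

    def __init__(self, layers: list):
        self.layers = layers
        self.loss_fn = SoftmaxCrossEntropy()

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        chunks = [
            softmax(self.forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def fit(
        self,
        x: np.ndarray,
        labels: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float,
        seed: int = 0,
    ) -> list[float]:
        """Train; returns the mean loss per epoch (length ``epochs``)."""
        rng = np.random.default_rng(seed)
        opt = Adam(lr=lr)
        n = len(x)
        trace: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.forward(x[idx], train=True)
                losses.append(self.loss_fn.loss(logits, labels[idx]))
                grad = self.loss_fn.backward()
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step(self.params())
            trace.append(float(np.mean(losses)))
        return trace
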