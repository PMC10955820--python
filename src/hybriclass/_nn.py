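"""A minimal feed-forward neural-network engine on numpy.

The package needs exactly three small networks (a LeNet-5 image backbone,
a two-layer convolutional yield regressor and a two-layer linear encoder),
trained on a single CPU with strict run-to-run determinism.  This module
provides the handful of layers they require — 2-D convolution via im2col,
2x2 max pooling, dense layers, ReLU — each exposing an explicit
``forward``/``backward`` pair, plus an Adam optimizer.  ``backward``
returns the gradient with respect to the layer input, so a frozen network
can be differentiated through (the encoder is trained through the frozen
yield predictor this way).

All parameters and activations are float64; initialization is He-uniform
driven by a caller-supplied :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless by default, with empty parameter lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = _he_uniform(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Conv2d(Layer):
    """Stride-1 2-D convolution with independent height/width zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        padding: tuple[int, int],
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        self.w = _he_uniform(rng, (out_channels, in_channels, kh, kw), fan_in)
        self.b = np.zeros(out_channels)
        self.kernel = kernel
        self.padding = padding
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._col: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        kh, kw = self.kernel
        ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        oh = h + 2 * ph - kh + 1
        ow = w + 2 * pw - kw + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        # (n, c, oh, ow, kh, kw) -> (n*oh*ow, c*kh*kw)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
        self._col = col
        self._x_shape = x.shape
        y = col @ self.w.reshape(self.w.shape[0], -1).T + self.b
        return y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        kh, kw = self.kernel
        ph, pw = self.padding
        f = self.w.shape[0]
        oh, ow = dy.shape[2], dy.shape[3]
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, f)
        self.grads[0][...] = (dyf.T @ self._col).reshape(self.w.shape)
        self.grads[1][...] = dyf.sum(axis=0)
        dcol = (dyf @ self.w.reshape(f, -1)).reshape(n, oh, ow, c, kh, kw)
        dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
        for ki in range(kh):
            for kj in range(kw):
                dxp[:, :, ki : ki + oh, kj : kj + ow] += dcol[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, ph : ph + h, pw : pw + w]


class GlobalAvgPoolW(Layer):
    """Mean over the width axis of an (n, c, 1, w) activation -> (n, c)."""

    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = np.argmax(xr, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("state dict does not match architecture")
        for i, p in enumerate(params):
            p[...] = state[f"p{i}"]

    def checksum(self) -> float:
        """Order-sensitive parameter digest for frozen-weights assertions."""
        return float(sum(np.sum(np.abs(p)) + i for i, p in enumerate(self.params)))


class Adam:
    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
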