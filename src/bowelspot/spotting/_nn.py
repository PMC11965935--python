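"""Minimal numpy building blocks for the 1-D segmentation network.

Implements exactly what the tiny encoder-decoder needs: strided 1-D
convolutions with hand-written backprop (tap-loop formulation, efficient for
small kernels), ReLU, nearest-neighbour x2 upsampling, and Adam. Tensors are
laid out [batch, channels, time].
"""

from __future__ import annotations

import numpy as np


class Conv1d:
    """1-D convolution, 'same'-style zero padding (pad = k // 2)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        # He initialisation (fan-in = c_in * k)
        self.W = rng.normal(0.0, np.sqrt(2.0 / (c_in * k)), size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.stride = stride
        self.pad = k // 2
        self._x_pad: np.ndarray | None = None
        self._t_in: int = 0

    @property
    def params(self):
        return [self.W, self.b]

    def out_len(self, t_in: int) -> int:
        return (t_in + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b_sz, _, t_in = x.shape
        x_pad = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        t_out = self.out_len(t_in)
        y = np.broadcast_to(self.b[None, :, None], (b_sz, len(self.b), t_out)).copy()
        hi = self.stride * (t_out - 1) + 1
        for j in range(self.k):
            xs = x_pad[:, :, j : j + hi : self.stride]  # [B, C_in, T_out]
            # [B, T_out, C_in] @ [C_in, C_out] -> accumulate as [B, C_out, T_out]
            y += np.matmul(xs.transpose(0, 2, 1), self.W[:, :, j].T).transpose(0, 2, 1)
        if train:
            self._x_pad = x_pad
            self._t_in = t_in
        return y

    def backward(self, dy: np.ndarray):
        """Returns dx; accumulates dW, db on self."""
        assert self._x_pad is not None, "forward(train=True) must precede backward"
        x_pad = self._x_pad
        t_out = dy.shape[2]
        hi = self.stride * (t_out - 1) + 1
        self.dW = np.zeros_like(self.W)
        self.db = dy.sum(axis=(0, 2))
        dx_pad = np.zeros_like(x_pad)
        for j in range(self.k):
            xs = x_pad[:, :, j : j + hi : self.stride]
            # dW[o,c,j] = sum_{b,t} dy[b,o,t] * xs[b,c,t]
            self.dW[:, :, j] = np.einsum("bot,bct->oc", dy, xs, optimize=True)
            dx_pad[:, :, j : j + hi : self.stride] += np.einsum(
                "oc,bot->bct", self.W[:, :, j], dy, optimize=True
            )
        self._x_pad = None
        return dx_pad[:, :, self.pad : self.pad + self._t_in]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos


class Upsample2x:
    """Nearest-neighbour x2 along time; backward sums gradient pairs."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy[:, :, 0::2] + dy[:, :, 1::2]


class Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.95, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.weight_decay * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
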