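"""Layers and optimiser for the recurrent behaviour models.

Sequences are represented as lists of 2-D tensors, one (batch, features)
tensor per time step; this keeps the autodiff engine strictly 2-D.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, softmax_rows


def glorot_uniform(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Layer:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Tensor(glorot_uniform(rng, n_in, n_out))
        self.b = Tensor(np.zeros((1, n_out)))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W + self.b
        if self.activation == "relu":
            y = y.relu()
        elif self.activation == "tanh":
            y = y.tanh()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y

    def parameters(self):
        return [self.W, self.b]


class LSTM(Layer):
    """Single LSTM layer over a list of per-step (batch, n_in) tensors.

    Gate order in the fused weight matrices is [input, forget, cell, output];
    the forget-gate bias is initialised to 1, the usual stabiliser.
    """

    def __init__(self, n_in: int, units: int, return_sequences: bool = False,
                 go_backwards: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.units = units
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self.W = Tensor(glorot_uniform(rng, n_in, 4 * units))
        self.U = Tensor(glorot_uniform(rng, units, 4 * units))
        b = np.zeros((1, 4 * units))
        b[0, units : 2 * units] = 1.0
        self.b = Tensor(b)

    def __call__(self, steps: list[Tensor]) -> list[Tensor] | Tensor:
        n = steps[0].shape[0]
        u = self.units
        h = Tensor(np.zeros((n, u)))
        c = Tensor(np.zeros((n, u)))
        seq = list(reversed(steps)) if self.go_backwards else steps
        outputs: list[Tensor] = []
        for x in seq:
            z = x @ self.W + h @ self.U + self.b
            i = z[:, :u].sigmoid()
            f = z[:, u : 2 * u].sigmoid()
            g = z[:, 2 * u : 3 * u].tanh()
            o = z[:, 3 * u :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h)
        if self.go_backwards:
            outputs = list(reversed(outputs))
        return outputs if self.return_sequences else outputs[-1]

    def parameters(self):
        return [self.W, self.U, self.b]


class Conv1D(Layer):
    """1-D convolution over the time axis (valid padding, stride 1)."""

    def __init__(self, n_in: int, filters: int, kernel_size: int,
                 activation: str | None = "relu", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.kernel_size = kernel_size
        self.W = Tensor(glorot_uniform(rng, kernel_size * n_in, filters))
        self.b = Tensor(np.zeros((1, filters)))
        self.activation = activation

    def __call__(self, steps: list[Tensor]) -> list[Tensor]:
        k = self.kernel_size
        if len(steps) < k:
            raise ValueError(f"sequence of length {len(steps)} shorter than kernel {k}")
        out = []
        for i in range(len(steps) - k + 1):
            window = concat(steps[i : i + k], axis=1)
            y = window @ self.W + self.b
            if self.activation == "relu":
                y = y.relu()
            out.append(y)
        return out

    def parameters(self):
        return [self.W, self.b]


class AdditiveAttention(Layer):
    """Additive (tanh-scored) attention over time steps.

    score_i = v . tanh(W h_i + b); alphas = softmax over steps; each step's
    hidden state is re-weighted by its alpha, preserving the sequence shape
    so a second recurrent layer can consume it.
    """

    def __init__(self, n_in: int, units: int = 32, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Tensor(glorot_uniform(rng, n_in, units))
        self.b = Tensor(np.zeros((1, units)))
        self.v = Tensor(glorot_uniform(rng, units, 1))
        self.last_alphas: np.ndarray | None = None

    def __call__(self, steps: list[Tensor]) -> list[Tensor]:
        scores = [ (s @ self.W + self.b).tanh() @ self.v for s in steps ]  # (n,1) each
        alphas = softmax_rows(concat(scores, axis=1))  # (n, T)
        self.last_alphas = alphas.data
        return [s * alphas[:, i : i + 1] for i, s in enumerate(steps)]

    def parameters(self):
        return [self.W, self.b, self.v]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 0.1,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
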