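"""Layers of the read-origin network, built on the autodiff Tensor.

The network consumes L x 5 one-hot read encodings and produces one logit
per read.  Layer order mirrors the model: 1D convolution over the sequence
-> scaled dot-product multi-head attention -> bidirectional LSTM -> linear
head.  All weights are float32 numpy arrays; initialization is Glorot
uniform from a caller-supplied Generator so runs are reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Conv1d",
    "MultiHeadAttention",
    "BiLSTM",
    "Linear",
    "Adam",
    "scaled_dot_product_attention",
    "lstm_step",
]


def _glorot(rng, fan_in: int, fan_out: int, shape) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(np.float32), requires_grad=True)


class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError


class Conv1d(Module):
    """1D convolution along the read, stride 1, no padding.

    Input (B, L, C_in) -> output (B, L - k + 1, C_out).  Implemented as an
    unfold into k*C_in columns followed by a matmul, which is also how the
    gradient with respect to the input is recovered.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng):
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = _glorot(
            rng, kernel_size * in_channels, out_channels, (kernel_size * in_channels, out_channels)
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.unfold(self.kernel_size) @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


def scaled_dot_product_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V on (..., T, d_k) tensors."""
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * (1.0 / math.sqrt(d_k))
    return scores.softmax(axis=-1) @ v


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product self-attention with output projection."""

    def __init__(self, d_model: int, n_heads: int, rng):
        if d_model % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide d_model={d_model}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.w_q = _glorot(rng, d_model, d_model, (d_model, d_model))
        self.w_k = _glorot(rng, d_model, d_model, (d_model, d_model))
        self.w_v = _glorot(rng, d_model, d_model, (d_model, d_model))
        self.w_o = _glorot(rng, d_model, d_model, (d_model, d_model))

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        q = self._split(x @ self.w_q, B, T)
        k = self._split(x @ self.w_k, B, T)
        v = self._split(x @ self.w_v, B, T)
        heads = scaled_dot_product_attention(q, k, v)  # (B, h, T, d_k)
        merged = heads.transpose(0, 2, 1, 3).reshape(B, T, self.d_model)
        return merged @ self.w_o

    def parameters(self):
        return [self.w_q, self.w_k, self.w_v, self.w_o]


def lstm_step(x_t: Tensor, h_prev: Tensor, c_prev: Tensor, w_x: Tensor, w_h: Tensor, b: Tensor):
    """One LSTM step with gate order (input, forget, cell, output):

        i = sigmoid(W_ii x + b_i + W_hi h)      f = sigmoid(W_if x + b_f + W_hf h)
        g = tanh  (W_ig x + b_g + W_hg h)       o = sigmoid(W_io x + b_o + W_ho h)
        c = f * c_prev + i * g                  h = o * tanh(c)
    """
    H = h_prev.shape[-1]
    z = x_t @ w_x + h_prev @ w_h + b
    i = z[:, 0 * H : 1 * H].sigmoid()
    f = z[:, 1 * H : 2 * H].sigmoid()
    g = z[:, 2 * H : 3 * H].tanh()
    o = z[:, 3 * H : 4 * H].sigmoid()
    c = f * c_prev + i * g
    h = o * c.tanh()
    return h, c


class _LSTMDirection(Module):
    def __init__(self, d_in: int, hidden: int, rng):
        self.hidden = hidden
        self.w_x = _glorot(rng, d_in, 4 * hidden, (d_in, 4 * hidden))
        self.w_h = _glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden))
        self.b = Tensor(np.zeros(4 * hidden, dtype=np.float32), requires_grad=True)

    def run(self, xs: list[Tensor], B: int) -> Tensor:
        h = Tensor(np.zeros((B, self.hidden), dtype=np.float32))
        c = Tensor(np.zeros((B, self.hidden), dtype=np.float32))
        for x_t in xs:
            h, c = lstm_step(x_t, h, c, self.w_x, self.w_h, self.b)
        return h

    def parameters(self):
        return [self.w_x, self.w_h, self.b]


class BiLSTM(Module):
    """(Bi)directional LSTM returning the final hidden state(s).

    Forward direction reads the sequence left to right and returns h_T;
    the backward direction reads right to left.  Output is the concat of
    final hidden states, shape (B, 2H) (or (B, H) if unidirectional).
    """

    def __init__(self, d_in: int, hidden: int, rng, bidirectional: bool = True):
        self.fwd = _LSTMDirection(d_in, hidden, rng)
        self.bwd = _LSTMDirection(d_in, hidden, rng) if bidirectional else None

    @property
    def out_dim(self) -> int:
        return self.fwd.hidden * (2 if self.bwd is not None else 1)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        steps = [x[:, t, :] for t in range(T)]
        h_f = self.fwd.run(steps, B)
        if self.bwd is None:
            return h_f
        h_b = self.bwd.run(steps[::-1], B)
        return concat([h_f, h_b], axis=-1)

    def parameters(self):
        params = self.fwd.parameters()
        if self.bwd is not None:
            params += self.bwd.parameters()
        return params


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng):
        self.weight = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
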