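"""Neural-network layers built on the :mod:`memtype.nn.autograd` engine.

Layers follow the conventions of the mainstream deep-learning frameworks:
channels-last tensors, glorot-uniform kernel initialisation, orthogonal
recurrent kernels with a unit forget-gate bias, inverted dropout, and
batch normalisation with running statistics for inference.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_arrays(self) -> List[np.ndarray]:
        """Trainable parameters plus non-trainable buffers, in stable order."""
        arrays = [p.data for p in self.parameters()]
        for value in vars(self).values():
            for m in _collect_modules(value):
                arrays.extend(m._buffers())
        arrays.extend(self._buffers())
        return arrays

    def _buffers(self) -> List[np.ndarray]:
        return []


def _collect(value) -> List[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: List[Tensor] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_modules(value) -> List["Module"]:
    if isinstance(value, Module):
        mods = [value]
        for v in vars(value).values():
            mods.extend(_collect_modules(v))
        return mods
    if isinstance(value, (list, tuple)):
        out: List[Module] = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = Tensor(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1D(Module):
    """1D convolution, channels last; ``same`` or ``valid`` padding."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 stride: int, padding: str, rng: np.random.Generator):
        fan_in = kernel * in_channels
        self.w = Tensor(glorot_uniform(rng, (kernel, in_channels, filters),
                                       fan_in, filters), requires_grad=True)
        self.b = Tensor(np.zeros(filters), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.w, self.b, stride=self.stride,
                         padding=self.padding)


class Conv2D(Module):
    """2D valid convolution with stride 1 (all this package needs)."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        fan_in = kernel * kernel * in_channels
        self.w = Tensor(glorot_uniform(rng, (kernel, kernel, in_channels, filters),
                                       fan_in, filters), requires_grad=True)
        self.b = Tensor(np.zeros(filters), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d_valid(x, self.w, self.b)


class BatchNorm(Module):
    """Batch normalisation over all axes except the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.99,
                 eps: float = 1e-3):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def _buffers(self) -> List[np.ndarray]:
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean[:] = m * self.running_mean + (1 - m) * mean.data.ravel()
            self.running_var[:] = m * self.running_var + (1 - m) * var.data.ravel()
            xhat = centered / ag.sqrt(var + self.eps)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class LSTM(Module):
    """Single-direction LSTM.

    Gate algebra (logistic gates, tanh candidates):

        f_t = sigma(W_f . [h_{t-1}, x_t] + b_f)
        i_t = sigma(W_i . [h_{t-1}, x_t] + b_i)
        c~_t = tanh(W_C . [h_{t-1}, x_t] + b_C)
        C_t = f_t * C_{t-1} + i_t * c~_t
        o_t = sigma(W_o . [h_{t-1}, x_t] + b_o)
        h_t = o_t * tanh(C_t)

    ``dropout`` drops input features with one mask shared across
    timesteps (the convention of the major frameworks).  Gate order in
    the fused kernel is [i, f, c, o]; the forget-gate bias starts at 1.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 dropout: float = 0.0, go_backwards: bool = False):
        h = units
        self.kernel = Tensor(glorot_uniform(rng, (input_dim, 4 * h),
                                            input_dim, 4 * h), requires_grad=True)
        rec = np.concatenate([orthogonal(rng, h) for _ in range(4)], axis=1)
        self.recurrent = Tensor(rec, requires_grad=True)
        bias = np.zeros(4 * h)
        bias[h:2 * h] = 1.0  # forget gate
        self.bias = Tensor(bias, requires_grad=True)
        self.units = h
        self.dropout = dropout
        self.go_backwards = go_backwards

    def _step(self, xt: Tensor, h: Tensor, c: Tensor):
        z = xt @ self.kernel + h @ self.recurrent + self.bias
        u = self.units
        i = ag.sigmoid(z[:, :u])
        f = ag.sigmoid(z[:, u:2 * u])
        cand = ag.tanh(z[:, 2 * u:3 * u])
        o = ag.sigmoid(z[:, 3 * u:])
        c_new = f * c + i * cand
        h_new = o * ag.tanh(c_new)
        return h_new, c_new, (i, f, cand, o)

    def __call__(self, x: Tensor, training: bool,
                 rng: Optional[np.random.Generator] = None,
                 return_sequences: bool = True) -> Tensor:
        n, t, _ = x.shape
        if training and self.dropout > 0.0:
            x = ag.dropout(x, self.dropout, rng, training)
        h = Tensor(np.zeros((n, self.units)))
        c = Tensor(np.zeros((n, self.units)))
        order = range(t - 1, -1, -1) if self.go_backwards else range(t)
        outputs: List[Tensor] = []
        for step in order:
            h, c, _ = self._step(x[:, step, :], h, c)
            outputs.append(h)
        if not return_sequences:
            return h
        if self.go_backwards:
            outputs = outputs[::-1]
        return ag.stack(outputs, axis=1)

    def gate_trace(self, x: np.ndarray) -> dict:
        """Run the recurrence in plain NumPy and record every gate.

        Returns per-step arrays ``i, f, candidate, o, c, h`` of shape
        (T, N, units); used to audit the gate contract.
        """
        n, t, _ = x.shape
        h = np.zeros((n, self.units))
        c = np.zeros((n, self.units))
        trace = {k: [] for k in ("i", "f", "candidate", "o", "c", "h")}
        order = range(t - 1, -1, -1) if self.go_backwards else range(t)
        for step in order:
            z = x[:, step, :] @ self.kernel.data + h @ self.recurrent.data + self.bias.data
            u = self.units
            i = 1 / (1 + np.exp(-z[:, :u]))
            f = 1 / (1 + np.exp(-z[:, u:2 * u]))
            cand = np.tanh(z[:, 2 * u:3 * u])
            o = 1 / (1 + np.exp(-z[:, 3 * u:]))
            c = f * c + i * cand
            h = o * np.tanh(c)
            for k, v in zip(("i", "f", "candidate", "o", "c", "h"),
                            (i, f, cand, o, c, h)):
                trace[k].append(v)
        return {k: np.stack(v) for k, v in trace.items()}


class Bidirectional(Module):
    """Wraps a forward and a backward LSTM; concatenates along features."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        self.forward = LSTM(input_dim, units, rng, dropout=dropout)
        self.backward = LSTM(input_dim, units, rng, dropout=dropout,
                             go_backwards=True)

    def __call__(self, x: Tensor, training: bool,
                 rng: Optional[np.random.Generator] = None,
                 return_sequences: bool = True) -> Tensor:
        fwd = self.forward(x, training, rng, return_sequences)
        bwd = self.backward(x, training, rng, return_sequences)
        axis = 2 if return_sequences else 1
        return ag.concatenate([fwd, bwd], axis=axis)
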