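"""The evolutionary-information model: 2D convs -> capsules -> routing.

A fixed-length PSSM (``1500 x 20``, one channel) passes through two
valid 5x5 convolutions with average pooling (256 then 128 filters,
dropout 0.5 after each conv activation), giving a ``372 x 2 x 128``
feature tensor.  A 1x1 convolutional PrimaryCaps stage with 4 capsule
channels of dimension 16 reshapes this to 2976 sixteen-dimensional
capsules.  Dynamic routing (3 iterations) couples them to 8 protein-type
capsules of dimension 16; each output capsule's Euclidean norm is the
class score, trained with the margin loss (m+ = 0.9, m- = 0.1,
lambda = 0.5) under Adam at learning rate 1e-4.

The squashing nonlinearity maps a capsule's total input ``s`` to a
same-direction vector of norm ``||s||^2 / (1 + ||s||^2)`` - strictly
increasing in ``||s||`` and bounded by 1.  An alternative "as_printed"
mode implementing the non-monotone variant ``s / (1 + ||s||^2)``
(whose norm peaks at 0.5) is retained for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import TrainingDiverged
from .evaluation import overall_success_rate
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv2D, Module
from .nn.optim import Adam
from .training import (History, TrainConfig, labels_to_onehot,
                       minibatch_indices, restore, snapshot)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def conv_pool_output_shape(in_shape: Sequence[int],
                           kernel: Union[int, Sequence[int]],
                           stride: int = 1, padding: str = "valid",
                           pool: Optional[int] = None) -> Tuple[int, ...]:
    """Spatial output shape of a conv (+ optional pooling) stage.

    ``valid``: out = floor((in - kernel) / stride) + 1 per axis;
    ``same``:  out = ceil(in / stride).  Pooling floor-divides by the
    pool size.  Raises on a kernel larger than the input under valid
    padding.
    """
    if padding not in ("valid", "same"):
        raise ValueError("padding must be 'valid' or 'same'")
    in_shape = tuple(int(d) for d in in_shape)
    if isinstance(kernel, int):
        kernel = (kernel,) * len(in_shape)
    out = []
    for dim, k in zip(in_shape, kernel):
        if dim < 1:
            raise ValueError("dimensions must be positive")
        if padding == "valid":
            if k > dim:
                raise ValueError(f"kernel {k} larger than input {dim} "
                                 "under valid padding")
            o = (dim - k) // stride + 1
        else:
            o = -(-dim // stride)
        if pool is not None:
            o = o // pool
        out.append(o)
    return tuple(out)


# ---------------------------------------------------------------------------
# capsule primitives
# ---------------------------------------------------------------------------

def squash(s, axis: int = -1, mode: str = "norm_squared", eps: float = 1e-12):
    """Capsule squashing nonlinearity.

    Default mode scales ``s`` to norm ``||s||^2 / (1 + ||s||^2)``; the
    "as_printed" mode computes ``s / (1 + ||s||^2)``.  Zero maps to zero
    in both modes with no division hazard.  Accepts a Tensor (autodiff)
    or a plain ndarray.
    """
    was_array = not isinstance(s, Tensor)
    t = Tensor(s) if was_array else s
    norm_sq = ag.tensor_sum(t * t, axis=axis, keepdims=True)
    if mode == "norm_squared":
        factor = ag.sqrt(norm_sq + eps) / (norm_sq + 1.0)
    elif mode == "as_printed":
        factor = 1.0 / (norm_sq + 1.0)
    else:
        raise ValueError(f"unknown squash mode {mode!r}")
    out = t * factor
    return out.data if was_array else out


def dynamic_routing(u_hat, iterations: int = 3,
                    squash_mode: str = "norm_squared"):
    """Routing-by-agreement between input and output capsules.

    ``u_hat``: prediction vectors of shape (N, I, J, D) - input capsule
    ``i``'s prediction for output capsule ``j``.  Logits ``b`` start at
    zero; each round computes couplings ``c = softmax_J(b)`` (so the
    first round couples uniformly, 1/J per output capsule), the weighted
    sums ``s_j = sum_i c_ij u_hat_j|i``, squashed outputs ``V_j``, and
    the agreement update ``b_ij += u_hat_j|i . V_j``.  Returns the final
    ``(V, c)``.
    """
    if iterations < 1:
        raise ValueError("routing needs at least one iteration")
    was_array = not isinstance(u_hat, Tensor)
    u = Tensor(u_hat) if was_array else u_hat
    n, i_caps, j_caps, _ = u.shape
    b = Tensor(np.zeros((n, i_caps, j_caps)))
    v = c = None
    for _ in range(iterations):
        c = ag.softmax(b, axis=2)
        s = ag.einsum("nij,nijd->njd", c, u)
        v = squash(s, axis=-1, mode=squash_mode)
        b = b + ag.einsum("nijd,njd->nij", u, v)
    if was_array:
        return v.data, c.data
    return v, c


@dataclass(frozen=True)
class MarginLossParams:
    """Margin-loss hyperparameters (reference defaults)."""

    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.m_minus < self.m_plus < 1.0):
            raise ValueError("require 0 < m_minus < m_plus < 1")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def margin_loss(norms: Sequence[float], label: int,
                params: MarginLossParams = MarginLossParams()) -> float:
    """Per-sample margin loss over the k capsule norms.

    ``L = sum_c [ T_c max(0, m+ - ||V_c||)^2
                  + lambda (1 - T_c) max(0, ||V_c|| - m-)^2 ]``
    with ``T_c = 1`` for the true class.  Norms must lie in [0, 1].
    """
    norms = np.asarray(norms, dtype=float)
    if norms.min() < 0.0 or norms.max() > 1.0:
        raise ValueError("capsule norms must lie in [0, 1]")
    if not 1 <= label <= len(norms):
        raise ValueError(f"label {label} outside 1..{len(norms)}")
    t = np.zeros(len(norms))
    t[label - 1] = 1.0
    pos = np.maximum(0.0, params.m_plus - norms) ** 2
    neg = np.maximum(0.0, norms - params.m_minus) ** 2
    return float(np.sum(t * pos + params.lam * (1.0 - t) * neg))


def margin_loss_batch(norms: Tensor, onehot: np.ndarray,
                      params: MarginLossParams = MarginLossParams()) -> Tensor:
    """Differentiable batch mean of per-sample margin-loss sums."""
    t = Tensor(onehot)
    pos = ag.relu(params.m_plus - norms)
    neg = ag.relu(norms - params.m_minus)
    per_class = t * pos * pos + params.lam * (1.0 - t) * neg * neg
    return ag.tensor_sum(per_class, axis=1).mean()


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class EvoModelSpec:
    """Architecture + optimiser hyperparameters (defaults = full-scale)."""

    T: int = 1500
    width: int = 20
    n_classes: int = 8
    conv1_filters: int = 256
    conv2_filters: int = 128
    kernel: int = 5
    pool: int = 2
    dropout: float = 0.5
    caps_channels: int = 4
    caps_dim: int = 16
    out_caps_dim: int = 16
    routing_iterations: int = 3
    squash_mode: str = "norm_squared"
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    @property
    def spatial_shape(self) -> Tuple[int, int]:
        """Spatial shape after the conv/pool stack (372 x 2 at full scale)."""
        s1 = conv_pool_output_shape((self.T, self.width), self.kernel,
                                    pool=self.pool)
        return conv_pool_output_shape(s1, self.kernel, pool=self.pool)

    @property
    def primary_capsule_count(self) -> int:
        h, w = self.spatial_shape
        return h * w * self.caps_channels

    def scaled_down(self, **overrides) -> "EvoModelSpec":
        """A small configuration for CPU-scale experiments."""
        base = dict(T=200, width=20, n_classes=4, conv1_filters=32,
                    conv2_filters=32, dropout=0.2, caps_channels=2,
                    caps_dim=8, out_caps_dim=8, lr=1e-3, seed=self.seed)
        base.update(overrides)
        return EvoModelSpec(**base)


class EvolutionaryModel(Module):
    """Callable model handle; build with :func:`build_evolutionary_model`."""

    def __init__(self, spec: EvoModelSpec):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.conv1 = Conv2D(1, spec.conv1_filters, spec.kernel, rng)
        self.conv2 = Conv2D(spec.conv1_filters, spec.conv2_filters,
                            spec.kernel, rng)
        self.primary = Conv2D(spec.conv2_filters,
                              spec.caps_channels * spec.caps_dim, 1, rng)
        i_caps = spec.primary_capsule_count
        self.routing_w = Tensor(
            rng.normal(0.0, 0.1, size=(i_caps, spec.n_classes,
                                       spec.out_caps_dim, spec.caps_dim)),
            requires_grad=True)
        self._rng = rng

    def forward(self, x: Tensor, training: bool = False,
                return_couplings: bool = False):
        """Capsule norms (N, k) for a batch of (N, T, 20) profiles."""
        if (x.shape[1], x.shape[2]) != (self.spec.T, self.spec.width):
            raise ValueError(f"input shape {x.shape[1:]} does not match "
                             f"spec {(self.spec.T, self.spec.width)}")
        n = x.shape[0]
        h = x.reshape((n, self.spec.T, self.spec.width, 1))
        h = ag.relu(self.conv1(h))
        h = ag.dropout(h, self.spec.dropout, self._rng, training)
        h = ag.avg_pool2d(h, self.spec.pool)
        h = ag.relu(self.conv2(h))
        h = ag.dropout(h, self.spec.dropout, self._rng, training)
        h = ag.avg_pool2d(h, self.spec.pool)
        h = self.primary(h)                       # (N, H', W', ch * dim)
        hh, ww = self.spec.spatial_shape
        u = h.reshape((n, hh * ww * self.spec.caps_channels,
                       self.spec.caps_dim))
        u = squash(u, axis=-1, mode=self.spec.squash_mode)
        u_hat = ag.einsum("ijod,nid->nijo", self.routing_w, u)
        v, c = dynamic_routing(u_hat, self.spec.routing_iterations,
                               self.spec.squash_mode)
        norms = ag.l2_norm(v, axis=-1)
        if return_couplings:
            return norms, v, c
        return norms


def build_evolutionary_model(spec: EvoModelSpec) -> EvolutionaryModel:
    return EvolutionaryModel(spec)


def predict_proba_caps(model: EvolutionaryModel, inputs: np.ndarray,
                       normalize: bool = False,
                       batch_size: int = 64) -> np.ndarray:
    """Per-class capsule-norm scores; optionally renormalised to sum 1.

    Raw scores lie in [0, 1) (squash range); the normalised mode divides
    each row by its sum, which preserves the argmax.
    """
    inputs = np.asarray(inputs, dtype=float)
    scores = []
    for start in range(0, len(inputs), batch_size):
        norms = model.forward(Tensor(inputs[start:start + batch_size]),
                              training=False)
        scores.append(norms.data)
    if not scores:
        return np.zeros((0, model.spec.n_classes))
    out = np.concatenate(scores)
    if normalize:
        out = out / out.sum(axis=1, keepdims=True)
    return out


def train_evolutionary_model(model: EvolutionaryModel,
                             train_set: Tuple[np.ndarray, np.ndarray],
                             val_set: Tuple[np.ndarray, np.ndarray],
                             config: Optional[TrainConfig] = None,
                             loss_params: MarginLossParams = MarginLossParams()
                             ) -> History:
    """Fit with margin loss/Adam; keep the best-validation-OSR weights."""
    config = config or TrainConfig()
    x_tr, y_tr = train_set
    x_val, y_val = val_set
    if len(x_val) == 0:
        raise ValueError("validation set is empty")
    k = model.spec.n_classes
    onehot_tr = labels_to_onehot(y_tr, k)
    params = model.parameters()
    opt = Adam(params, lr=model.spec.lr, beta1=model.spec.beta1,
               beta2=model.spec.beta2)
    shuffle_rng = np.random.default_rng(config.seed)
    state = model.state_arrays()
    history = History()
    best = snapshot(state)
    for epoch in range(config.epochs):
        losses = []
        for idx in minibatch_indices(len(x_tr), config.batch_size, shuffle_rng):
            opt.zero_grad()
            norms = model.forward(Tensor(x_tr[idx]), training=True)
            loss = margin_loss_batch(norms, onehot_tr[idx], loss_params)
            if not np.isfinite(loss.data):
                raise TrainingDiverged("margin loss is not finite")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_scores = predict_proba_caps(model, x_val)
        val_loss = float(np.mean([
            margin_loss(row, int(lbl), loss_params)
            for row, lbl in zip(np.clip(val_scores, 0.0, 1.0), y_val)]))
        val_pred = val_scores.argmax(axis=1) + 1
        val_osr = overall_success_rate(y_val, val_pred)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.val_osr.append(val_osr)
        if val_osr > history.best_val_osr:
            history.best_val_osr = val_osr
            history.best_epoch = epoch
            best = snapshot(state)
        if config.verbose:
            print(f"epoch {epoch}: loss {history.train_loss[-1]:.4f} "
                  f"val_osr {val_osr:.4f}")
        if (config.stop_at_val_osr is not None
                and val_osr >= config.stop_at_val_osr):
            break
    restore(state, best)
    return history
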