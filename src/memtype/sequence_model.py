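"""The sequence-information model: 1D conv -> Bi-LSTM x2 -> softmax.

Fixed-length encoded sequences (``T x C``; ``C = 20`` one-hot or ``C = d``
embedded) pass through a strided 1D convolution (256 filters, kernel 15,
stride 10, same padding, rectifier) that shortens a length-1500 input to
150 steps, then two bidirectional LSTM layers (128 units per direction,
input dropout 0.5), and a dense softmax over the 8 membrane-protein
types.  Batch normalisation follows the convolution and each recurrent
layer.  Trained with categorical cross-entropy under Adam
(lr 0.001, beta1 0.9, beta2 0.999, decay 0); the weights kept are those
of the epoch with the best validation overall success rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import TrainingDiverged
from .evaluation import overall_success_rate
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import BatchNorm, Bidirectional, Conv1D, Dense, Module
from .nn.optim import Adam
from .training import (History, TrainConfig, labels_to_onehot,
                       minibatch_indices, restore, snapshot)


def conv1d_same_length(T: int, stride: int) -> int:
    """Output length of a strided 'same'-padded convolution: ceil(T/stride)."""
    return math.ceil(T / stride)


@dataclass
class SequenceModelSpec:
    """Architecture + optimiser hyperparameters (defaults = full-scale)."""

    T: int = 1500
    channels: int = 20
    n_classes: int = 8
    conv_filters: int = 256
    kernel: int = 15
    stride: int = 10
    lstm_units: int = 128          # per direction
    dropout: float = 0.5
    batch_norm: bool = True
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def scaled_down(self, **overrides) -> "SequenceModelSpec":
        """A small configuration for CPU-scale experiments."""
        base = dict(T=200, channels=self.channels, n_classes=4,
                    conv_filters=64, kernel=15, stride=10, lstm_units=32,
                    dropout=0.2, lr=self.lr, seed=self.seed)
        base.update(overrides)
        return SequenceModelSpec(**base)


class SequenceModel(Module):
    """Callable model handle; build with :func:`build_sequence_model`."""

    def __init__(self, spec: SequenceModelSpec):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.conv = Conv1D(spec.channels, spec.conv_filters, spec.kernel,
                           spec.stride, "same", rng)
        self.bn_conv = BatchNorm(spec.conv_filters) if spec.batch_norm else None
        self.bi1 = Bidirectional(spec.conv_filters, spec.lstm_units, rng,
                                 dropout=spec.dropout)
        self.bn1 = BatchNorm(2 * spec.lstm_units) if spec.batch_norm else None
        self.bi2 = Bidirectional(2 * spec.lstm_units, spec.lstm_units, rng,
                                 dropout=spec.dropout)
        self.bn2 = BatchNorm(2 * spec.lstm_units) if spec.batch_norm else None
        self.head = Dense(2 * spec.lstm_units, spec.n_classes, rng)
        self._rng = rng

    @property
    def conv_length(self) -> int:
        return conv1d_same_length(self.spec.T, self.spec.stride)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        """Logits for a batch; ``x`` is (N, T, C)."""
        if x.shape[2] != self.spec.channels:
            raise ValueError(f"input has {x.shape[2]} channels, model expects "
                             f"{self.spec.channels}")
        h = ag.relu(self.conv(x))
        if self.bn_conv is not None:
            h = self.bn_conv(h, training)
        h = self.bi1(h, training, self._rng, return_sequences=True)
        if self.bn1 is not None:
            h = self.bn1(h, training)
        h = self.bi2(h, training, self._rng, return_sequences=False)
        if self.bn2 is not None:
            h = self.bn2(h, training)
        return self.head(h)

    def conv_feature_map(self, x: np.ndarray) -> np.ndarray:
        """Post-convolution activations (N, ceil(T/stride), filters)."""
        return ag.relu(self.conv(Tensor(x))).data


def build_sequence_model(spec: SequenceModelSpec) -> SequenceModel:
    return SequenceModel(spec)


def predict_proba_seq(model: SequenceModel, inputs: np.ndarray,
                      batch_size: int = 128) -> np.ndarray:
    """N x k class probabilities (inference mode: dropout off, BN frozen)."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 3 or inputs.shape[2] != model.spec.channels:
        raise ValueError("inputs must be (N, T, C) with channels matching "
                         "the training representation")
    probs = []
    for start in range(0, len(inputs), batch_size):
        logits = model.forward(Tensor(inputs[start:start + batch_size]),
                               training=False)
        probs.append(ag.softmax(logits).data)
    return np.concatenate(probs) if probs else np.zeros((0, model.spec.n_classes))


def train_sequence_model(model: SequenceModel,
                         train_set: Tuple[np.ndarray, np.ndarray],
                         val_set: Tuple[np.ndarray, np.ndarray],
                         config: Optional[TrainConfig] = None) -> History:
    """Fit with cross-entropy/Adam; keep the best-validation-OSR weights."""
    config = config or TrainConfig()
    x_tr, y_tr = train_set
    x_val, y_val = val_set
    if len(x_val) == 0:
        raise ValueError("validation set is empty")
    if len(x_tr) != len(y_tr):
        raise ValueError("training inputs and labels differ in length")
    k = model.spec.n_classes
    onehot_tr = labels_to_onehot(y_tr, k)
    onehot_val = labels_to_onehot(y_val, k)
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
            logits = model.forward(Tensor(x_tr[idx]), training=True)
            loss = ag.softmax_cross_entropy(logits, onehot_tr[idx])
            if not np.isfinite(loss.data):
                raise TrainingDiverged("sequence-model loss is not finite")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_probs = predict_proba_seq(model, x_val)
        val_loss = float(-np.mean(np.log(
            np.clip((val_probs * onehot_val).sum(axis=1), 1e-12, None))))
        val_pred = val_probs.argmax(axis=1) + 1
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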