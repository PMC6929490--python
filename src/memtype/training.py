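"""Shared training-loop machinery for the two network models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional

import numpy as np

from .nn.autograd import Tensor


@dataclass
class TrainConfig:
    """Options common to both model training loops.

    ``stop_at_val_osr`` enables early stopping once the validation
    overall success rate reaches the given level; the best-validation
    weights are retained either way.
    """

    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    stop_at_val_osr: Optional[float] = None
    verbose: bool = False


@dataclass
class History:
    """Per-epoch training record."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_osr: List[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_osr: float = -1.0

    def to_csv(self) -> str:
        lines = ["epoch,train_loss,val_loss,val_osr"]
        for i, (tl, vl, vo) in enumerate(zip(self.train_loss, self.val_loss,
                                             self.val_osr)):
            lines.append(f"{i},{tl:.6f},{vl:.6f},{vo:.6f}")
        return "\n".join(lines) + "\n"


def minibatch_indices(n: int, batch_size: int,
                      rng: np.random.Generator) -> Iterator[np.ndarray]:
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def snapshot(arrays: List[np.ndarray]) -> List[np.ndarray]:
    """Copy a model's state arrays (weights and buffers)."""
    return [a.copy() for a in arrays]


def restore(arrays: List[np.ndarray], saved: List[np.ndarray]) -> None:
    for a, s in zip(arrays, saved):
        a[...] = s


def labels_to_onehot(labels: np.ndarray, k: int) -> np.ndarray:
    """Class labels 1..k to an N x k one-hot matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 1 or labels.max() > k):
        raise ValueError(f"labels must lie in 1..{k}")
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out
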