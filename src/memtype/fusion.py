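"""Probability stacking of the sequence and evolutionary models.

The two base models each emit 8 class probabilities per protein; their
concatenation ``P(x) = (P^1_1..P^1_8, P^2_1..P^2_8)`` (sequence half
first) is the 16-dimensional meta-feature on which a multinomial
logistic-regression meta-classifier is trained.  Meta-training uses
base-model predictions on data the bases did not train on (the held-out
validation split, or out-of-fold predictions in K-fold mode), and the
meta-classifier's output is the final prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from sklearn.linear_model import LogisticRegression


@dataclass
class MetaClassifier:
    """Fitted multinomial logistic regression over 16 meta-features."""

    coef: np.ndarray           # (k, 16)
    intercept: np.ndarray      # (k,)
    classes: np.ndarray        # label values, ascending
    c_reg: float

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = features @ self.coef.T + self.intercept
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def build_meta_features(p_seq: np.ndarray, p_evo: np.ndarray) -> np.ndarray:
    """Concatenate base-model probability rows, sequence half first."""
    p_seq = np.asarray(p_seq, dtype=float)
    p_evo = np.asarray(p_evo, dtype=float)
    if p_seq.shape[0] != p_evo.shape[0]:
        raise ValueError("base-model outputs have different sample counts")
    return np.concatenate([p_seq, p_evo], axis=1)


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Renormalise capsule-norm rows to sum 1 (probability scale)."""
    scores = np.asarray(scores, dtype=float)
    return scores / scores.sum(axis=1, keepdims=True)


def train_meta(features: np.ndarray, labels: np.ndarray,
               c_reg: float = 10.0, seed: int = 0,
               max_iter: int = 2000) -> MetaClassifier:
    """Fit the multinomial logistic meta-classifier.

    ``c_reg`` is the inverse L2 strength; the default is a weak penalty
    that only stabilises the 16-feature fit.  The lbfgs solve is
    deterministic, so permuting sample order does not change the fit.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("meta-training needs at least 2 classes present")
    lr = LogisticRegression(C=c_reg, max_iter=max_iter, solver="lbfgs",
                            random_state=seed)
    lr.fit(np.asarray(features, dtype=float), labels)
    return MetaClassifier(coef=lr.coef_.copy(), intercept=lr.intercept_.copy(),
                          classes=lr.classes_.copy(), c_reg=c_reg)


def predict_fused(meta: Optional[MetaClassifier], p_seq: np.ndarray,
                  p_evo: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Meta-classifier probabilities and argmax labels for base outputs."""
    if meta is None:
        raise ValueError("meta-classifier has not been trained")
    features = build_meta_features(p_seq, p_evo)
    if features.shape[0] == 0:
        return np.zeros((0, len(meta.classes))), np.zeros(0, dtype=int)
    probs = meta.predict_proba(features)
    labels = meta.classes[probs.argmax(axis=1)]
    return probs, labels


def train_meta_kfold(p_seq_fn, p_evo_fn, x_seq: np.ndarray,
                     x_evo: np.ndarray, labels: np.ndarray,
                     n_folds: int = 5, seed: int = 0,
                     c_reg: float = 10.0) -> MetaClassifier:
    """Out-of-fold stacking: callables score each held-out fold.

    ``p_seq_fn(train_idx, test_idx)`` must return base probabilities for
    ``test_idx`` from a model trained without them (likewise
    ``p_evo_fn``).  Provided as an option; the default pipeline stacks
    on the validation split instead.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    folds = np.array_split(order, n_folds)
    feats = None
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        block = build_meta_features(p_seq_fn(train_idx, test_idx),
                                    p_evo_fn(train_idx, test_idx))
        if feats is None:
            feats = np.zeros((len(labels), block.shape[1]))
        feats[test_idx] = block
    return train_meta(feats, labels, c_reg=c_reg, seed=seed)


# -- persistence -------------------------------------------------------------

def save_meta(path: Union[str, Path], meta: MetaClassifier) -> None:
    payload = {"format": "memtype-meta-v1",
               "coef": meta.coef.tolist(),
               "intercept": meta.intercept.tolist(),
               "classes": meta.classes.tolist(),
               "c_reg": meta.c_reg}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_meta(path: Union[str, Path]) -> MetaClassifier:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "memtype-meta-v1":
        raise ValueError("unrecognised meta-classifier file format")
    return MetaClassifier(coef=np.array(payload["coef"]),
                          intercept=np.array(payload["intercept"]),
                          classes=np.array(payload["classes"]),
                          c_reg=payload["c_reg"])
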