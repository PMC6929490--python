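"""Run configuration, data splitting, and model persistence."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import yaml

from .capsule_model import EvolutionaryModel, EvoModelSpec
from .errors import ModelPersistenceError
from .sequence_model import SequenceModel, SequenceModelSpec

_FORMAT = "memtype-model-v1"


@dataclass
class RunConfig:
    """Paths, encoding choice and hyperparameters for a pipeline run.

    Hyperparameter defaults equal the full-scale model specifications;
    the validation fraction defaults to 20% of the training set.
    """

    fasta: Optional[str] = None
    labels: Optional[str] = None
    pssm_manifest: Optional[str] = None
    property_table: Optional[str] = None
    output_dir: str = "memtype_out"
    encoding: str = "one-hot"            # one-hot | embedding | random
    embedding_table: Optional[str] = None
    T: int = 1500
    val_fraction: float = 0.2
    split_mode: str = "stratified"
    seed: int = 0
    sequence_spec: Dict = field(default_factory=dict)
    evo_spec: Dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("validation fraction must lie in (0, 1)")
        if self.T < 1:
            raise ValueError("fixed length T must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def split_train_validation(labels: np.ndarray, fraction: float = 0.2,
                           mode: str = "stratified", seed: int = 0
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation index split.

    ``stratified`` holds out ``round(fraction * n_c)`` samples per class
    (a single-sample class stays in training, with a warning);
    ``overall`` holds out ``round(fraction * N)`` samples irrespective
    of class.  Deterministic given ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if mode not in ("stratified", "overall"):
        raise ValueError("mode must be 'stratified' or 'overall'")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    if mode == "overall":
        perm = rng.permutation(n)
        n_val = int(round(fraction * n))
        return np.sort(perm[n_val:]), np.sort(perm[:n_val])
    val_parts = []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if len(idx) == 1:
            warnings.warn(f"class {c} has a single sample; kept in training")
            continue
        n_val = int(round(fraction * len(idx)))
        val_parts.append(rng.permutation(idx)[:n_val])
    val_idx = np.sort(np.concatenate(val_parts)) if val_parts else np.array([], int)
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    return train_idx, val_idx


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model: Union[SequenceModel, EvolutionaryModel],
               path: Union[str, Path]) -> None:
    """Write weights (npz) plus a YAML sidecar describing the spec."""
    path = Path(path)
    if isinstance(model, SequenceModel):
        kind = "sequence"
    elif isinstance(model, EvolutionaryModel):
        kind = "evolutionary"
    else:
        raise TypeError(f"cannot persist object of type {type(model)}")
    arrays = model.state_arrays()
    np.savez(path.with_suffix(".npz"),
             **{f"arr_{i}": a for i, a in enumerate(arrays)})
    sidecar = {"format": _FORMAT, "kind": kind, "spec": asdict(model.spec),
               "n_arrays": len(arrays)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def load_model(path: Union[str, Path]
               ) -> Union[SequenceModel, EvolutionaryModel]:
    """Restore a model saved by :func:`save_model`.

    The restored model produces bit-identical predictions on any probe
    batch.  A missing/corrupt sidecar or a version mismatch raises
    :class:`ModelPersistenceError`.
    """
    path = Path(path)
    try:
        sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ModelPersistenceError(f"cannot read model sidecar: {exc}") from exc
    if not isinstance(sidecar, dict) or sidecar.get("format") != _FORMAT:
        raise ModelPersistenceError(
            f"unsupported model format {sidecar.get('format') if isinstance(sidecar, dict) else sidecar!r}; "
            f"expected {_FORMAT}")
    if sidecar["kind"] == "sequence":
        model: Union[SequenceModel, EvolutionaryModel] = SequenceModel(
            SequenceModelSpec(**sidecar["spec"]))
    elif sidecar["kind"] == "evolutionary":
        model = EvolutionaryModel(EvoModelSpec(**sidecar["spec"]))
    else:
        raise ModelPersistenceError(f"unknown model kind {sidecar['kind']!r}")
    with np.load(path.with_suffix(".npz")) as data:
        arrays = model.state_arrays()
        if len(data.files) != len(arrays) or sidecar.get("n_arrays") != len(arrays):
            raise ModelPersistenceError("weight file does not match the spec")
        for i, arr in enumerate(arrays):
            loaded = data[f"arr_{i}"]
            if loaded.shape != arr.shape:
                raise ModelPersistenceError("weight shapes do not match the spec")
            arr[...] = loaded
    return model
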