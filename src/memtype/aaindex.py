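"""Amino-acid embeddings learned from physicochemical property indexes.

One-hot residue encoding carries no notion of physicochemical similarity.
This module builds a dense alternative: take a published table of
per-residue property indexes (AAindex1 flat-file dialect, 20 residues by
P indexes, possibly with missing cells), drop every index containing a
missing value, z-score each remaining index over the 20 residues, train
a symmetric autoencoder on the 20 property vectors, and read each
residue's bottleneck activation out as its embedding vector.  A uniform
random baseline on [0, 1] is provided for control experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .errors import TrainingDiverged
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Dense, Module
from .nn.optim import Adam
from .seq_encoding import AMINO_ACIDS

#: residue order of the two value rows in an AAindex1 "I" record
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


@dataclass
class PropertyTable:
    """20 x P matrix of property indexes, rows in alphabetical residue order."""

    values: np.ndarray                    # (20, P) float
    index_ids: List[str]
    na_mask: np.ndarray = None            # (20, P) bool; False after filtering
    dropped_ids: List[str] = field(default_factory=list)
    center: Optional[np.ndarray] = None   # set by standardize()
    scale: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 20:
            raise ValueError("property table must have exactly 20 residue rows")
        if self.values.shape[1] != len(self.index_ids):
            raise ValueError("index_ids must match the number of columns")
        if self.na_mask is None:
            self.na_mask = np.zeros_like(self.values, dtype=bool)

    @property
    def n_indexes(self) -> int:
        return self.values.shape[1]


def _parse_aaindex_record(block: str) -> Tuple[str, np.ndarray]:
    """Parse one AAindex1 record; returns (accession, 20 values with NaN for NA)."""
    accession = None
    values: List[float] = []
    lines = block.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("I "):
            for row in lines[i + 1:i + 3]:
                for tok in row.split():
                    if tok.upper() == "NA":
                        values.append(np.nan)
                    else:
                        values.append(float(tok))
            i += 2
        i += 1
    if accession is None:
        raise ValueError("AAindex record lacks an 'H' accession line")
    if len(values) != 20:
        raise ValueError(f"AAindex record {accession}: expected 20 values, "
                         f"got {len(values)}")
    # reorder from AAindex row order to alphabetical order
    aaindex_order = _AAINDEX_ROW1 + _AAINDEX_ROW2
    ordered = np.empty(20)
    for pos, aa in enumerate(aaindex_order):
        ordered[AMINO_ACIDS.index(aa)] = values[pos]
    return accession, ordered


def load_property_table(source: Union[str, Path]) -> PropertyTable:
    """Load an AAindex1 flat file (or raw text), dropping any-NA indexes.

    Every index with one or more missing ('NA') cells is screened out;
    the retained values are the published numbers, unmodified.  Also
    accepts a plain TSV with a header of index ids and 20 residue rows.
    """
    text = source if isinstance(source, str) and "\n" in source \
        else Path(source).read_text()
    if not text.strip():
        raise ValueError("empty property table source")
    if "//" in text or text.lstrip().startswith("H "):
        cols: List[np.ndarray] = []
        ids: List[str] = []
        dropped: List[str] = []
        for block in text.split("//"):
            if not block.strip():
                continue
            acc, vals = _parse_aaindex_record(block)
            if np.isnan(vals).any():
                dropped.append(acc)
            else:
                ids.append(acc)
                cols.append(vals)
        if len(ids) < 2:
            raise ValueError("fewer than 2 indexes retained after NA filtering")
        return PropertyTable(values=np.stack(cols, axis=1), index_ids=ids,
                             dropped_ids=dropped)
    return _load_property_tsv(text)


def _load_property_tsv(text: str) -> PropertyTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    ids = lines[0].split("\t")[1:]
    rows = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows[parts[0]] = [np.nan if p.upper() == "NA" else float(p)
                          for p in parts[1:]]
    values = np.array([rows[aa] for aa in AMINO_ACIDS])
    keep = ~np.isnan(values).any(axis=0)
    dropped = [i for i, k in zip(ids, keep) if not k]
    ids = [i for i, k in zip(ids, keep) if k]
    if len(ids) < 2:
        raise ValueError("fewer than 2 indexes retained after NA filtering")
    return PropertyTable(values=values[:, keep], index_ids=ids,
                         dropped_ids=dropped)


def standardize(table: PropertyTable) -> PropertyTable:
    """Z-score each index over the 20 residues; drop constant columns.

    Raw AAindex scales differ by orders of magnitude, and an autoencoder
    trained on raw values degenerates to fitting the large-magnitude
    indexes, so per-index centering/scaling is applied before training.
    The affine parameters are stored so the transform can be inverted.
    """
    if table.n_indexes < 2:
        raise ValueError("standardize requires at least 2 indexes")
    center = table.values.mean(axis=0)
    scale = table.values.std(axis=0)
    keep = scale > 0
    if not keep.all():
        dropped = [i for i, k in zip(table.index_ids, keep) if not k]
        warnings.warn(f"dropping constant property indexes: {dropped}")
    values = (table.values[:, keep] - center[keep]) / scale[keep]
    return PropertyTable(values=values,
                         index_ids=[i for i, k in zip(table.index_ids, keep) if k],
                         dropped_ids=list(table.dropped_ids),
                         center=center[keep], scale=scale[keep])


def destandardize(table: PropertyTable) -> np.ndarray:
    """Invert :func:`standardize`; returns the raw 20 x P value matrix."""
    if table.center is None or table.scale is None:
        raise ValueError("table was not produced by standardize()")
    return table.values * table.scale + table.center


# ---------------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderSpec:
    """Symmetric autoencoder: P -> 128 -> 64 -> d -> 64 -> 128 -> P.

    Hidden layers use the rectifier; the bottleneck and the output layer
    are linear, so embeddings can take either sign and reconstruction is
    unconstrained on the z-scored property scale.  Trained with Adam on
    mean squared reconstruction error over exactly the 20 residue rows.
    """

    bottleneck_dim: int = 10
    hidden: Tuple[int, ...] = (128, 64)
    lr: float = 1e-3
    epochs: int = 1500
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.bottleneck_dim < 64:
            raise ValueError("bottleneck dimension must be in 1..63")


class Autoencoder(Module):
    def __init__(self, n_inputs: int, spec: AutoencoderSpec):
        rng = np.random.default_rng(spec.seed)
        widths = [n_inputs, *spec.hidden, spec.bottleneck_dim]
        self.encoder = [Dense(a, b, rng) for a, b in zip(widths, widths[1:])]
        dec_widths = [spec.bottleneck_dim, *reversed(spec.hidden), n_inputs]
        self.decoder = [Dense(a, b, rng) for a, b in zip(dec_widths, dec_widths[1:])]
        self.spec = spec

    def encode(self, x: Tensor) -> Tensor:
        for layer in self.encoder[:-1]:
            x = ag.relu(layer(x))
        return self.encoder[-1](x)          # linear bottleneck

    def forward(self, x: Tensor) -> Tensor:
        z = self.encode(x)
        for layer in self.decoder[:-1]:
            z = ag.relu(layer(z))
        return self.decoder[-1](z)          # linear output


def train_autoencoder(table: PropertyTable,
                      spec: AutoencoderSpec = AutoencoderSpec()
                      ) -> Tuple[Autoencoder, List[float]]:
    """Fit the autoencoder on the 20 residue rows (full batch, fixed seed).

    Returns the trained model and the per-epoch reconstruction losses.
    Deterministic given ``spec.seed``.
    """
    model = Autoencoder(table.n_indexes, spec)
    opt = Adam(model.parameters(), lr=spec.lr)
    x = table.values
    history: List[float] = []
    for _ in range(spec.epochs):
        opt.zero_grad()
        recon = model.forward(Tensor(x))
        diff = recon - Tensor(x)
        loss = (diff * diff).mean()
        if not np.isfinite(loss.data):
            raise TrainingDiverged("autoencoder reconstruction loss is not finite")
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    return model, history


# ---------------------------------------------------------------------------
# embedding tables
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingTable:
    """20 x d residue embedding with a provenance tag."""

    vectors: np.ndarray
    provenance: str    # autoencoder | random-baseline | identity

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != 20:
            raise ValueError("embedding table must have exactly 20 rows")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding table contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def extract_embedding(model: Autoencoder, table: PropertyTable) -> EmbeddingTable:
    """Read the bottleneck activation of each residue's property vector."""
    if table.n_indexes != model.encoder[0].w.shape[0]:
        raise ValueError("table width does not match the trained model")
    vectors = model.encode(Tensor(table.values)).data
    return EmbeddingTable(vectors=vectors, provenance="autoencoder")


def random_embedding(d: int, seed: int) -> EmbeddingTable:
    """Uniform [0, 1] baseline embedding, reproducible by seed."""
    if d < 1:
        raise ValueError("embedding dimension must be >= 1")
    rng = np.random.default_rng(seed)
    return EmbeddingTable(vectors=rng.random((20, d)),
                          provenance="random-baseline")


def identity_embedding() -> EmbeddingTable:
    """The 20 x 20 identity; embedding lookup reproduces one-hot rows."""
    return EmbeddingTable(vectors=np.eye(20), provenance="identity")


def write_embedding_tsv(path: Union[str, Path], table: EmbeddingTable) -> None:
    with open(path, "w") as fh:
        fh.write("# provenance: " + table.provenance + "\n")
        for aa, row in zip(AMINO_ACIDS, table.vectors):
            fh.write(aa + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_embedding_tsv(path: Union[str, Path]) -> EmbeddingTable:
    provenance = "unknown"
    rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# provenance:"):
                provenance = line.split(":", 1)[1].strip()
                continue
            parts = line.split()
            if parts:
                rows[parts[0]] = [float(v) for v in parts[1:]]
    vectors = np.array([rows[aa] for aa in AMINO_ACIDS])
    return EmbeddingTable(vectors=vectors, provenance=provenance)
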