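"""Synthetic labelled datasets with the structure the models assume.

Real membrane-protein benchmarks couple a class label to (a) residue
composition of the sequence and (b) a PSSM whose log-odds reflect that
composition.  The generator reproduces exactly that coupling: each class
owns a residue composition (a mixture of the uniform background and a
class-specific Dirichlet peak, with the mixing weight acting as a
separability dial), sequence lengths follow a log-normal clipped to
[50, 5000] whose defaults put ~98% of lengths below 1500, and PSSMs are
integer log-odds of a per-position mixture of the true residue and the
class composition, plus optional Gaussian noise, clipped to [-12, 12].

What the generator does *not* emulate: transmembrane topology, domain
order, homology between sequences, or PSI-BLAST's pseudo-count
machinery.  Passing tests on this data demonstrates that the models can
extract class-conditional compositional and profile signal, not that
they reach the published accuracies on curated benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .pssm import PSSMMatrix, write_ascii_pssm
from .seq_encoding import AMINO_ACIDS, write_fasta, write_labels_tsv

#: uniform background residue composition
BACKGROUND = np.full(20, 1.0 / 20.0)

#: Dataset-1-style training-set class sizes (largest:smallest ~ 55:1)
TABLE1_TRAIN_COUNTS = (610, 312, 24, 44, 1316, 151, 182, 610)


@dataclass
class LengthParams:
    """Clipped log-normal sequence-length model.

    Defaults (mu=6.0, sigma=0.64 on the log scale) give a median length
    of ~400 and put ~98% of draws below 1500 before clipping to
    [min_len, max_len] = [50, 5000].
    """

    mu: float = 6.0
    sigma: float = 0.64
    min_len: int = 50
    max_len: int = 5000

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raw = np.exp(rng.normal(self.mu, self.sigma, size=n))
        return np.clip(np.round(raw).astype(int), self.min_len, self.max_len)


@dataclass
class ClassProfile:
    """Residue composition and length model for one synthetic class."""

    composition: np.ndarray            # point on the 20-simplex
    lengths: LengthParams = field(default_factory=LengthParams)
    separability: float = 0.9

    def __post_init__(self):
        self.composition = np.asarray(self.composition, dtype=float)
        if not np.isclose(self.composition.sum(), 1.0):
            raise ValueError("composition must sum to 1")


@dataclass
class SyntheticDataset:
    sequences: List[str]
    labels: np.ndarray                 # values in 1..k
    ids: List[str]
    pssms: Optional[List[PSSMMatrix]] = None
    seed: Optional[int] = None


def make_class_profiles(k: int, separability: float, seed: int,
                        lengths: LengthParams | None = None,
                        peak_concentration: float = 0.3
                        ) -> List[ClassProfile]:
    """Draw ``k`` class compositions at the requested separability.

    Each composition is ``(1 - s) * background + s * peak`` with the peak
    drawn from a sparse symmetric Dirichlet, so pairwise total-variation
    distance between classes grows monotonically with ``s``; ``s = 0``
    collapses every class onto the uniform background.
    """
    if k < 2:
        raise ValueError("need at least 2 classes")
    if separability < 0:
        raise ValueError("separability must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = lengths or LengthParams()
    profiles = []
    for _ in range(k):
        peak = rng.dirichlet(np.full(20, peak_concentration))
        comp = (1.0 - separability) * BACKGROUND + separability * peak
        profiles.append(ClassProfile(composition=comp / comp.sum(),
                                     lengths=lengths,
                                     separability=separability))
    return profiles


def sample_dataset(profiles: Sequence[ClassProfile],
                   counts: Sequence[int], seed: int,
                   with_pssm: bool = False,
                   pssm_noise_sd: float = 1.0,
                   pssm_alpha: float = 0.6) -> SyntheticDataset:
    """Draw sequences (residues i.i.d. from each class composition).

    ``counts[c]`` sequences are drawn for class ``c + 1``; lengths come
    from each profile's length model.  With ``with_pssm`` a matched
    profile matrix is synthesised per sequence.
    """
    if len(counts) != len(profiles):
        raise ValueError("one count per class profile required")
    if any(c < 1 for c in counts):
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    residues = np.array(list(AMINO_ACIDS))
    sequences: List[str] = []
    labels: List[int] = []
    ids: List[str] = []
    pssms: List[PSSMMatrix] = []
    for c, (profile, n) in enumerate(zip(profiles, counts), start=1):
        lens = profile.lengths.sample(n, rng)
        for j, length in enumerate(lens):
            seq = "".join(rng.choice(residues, size=length, p=profile.composition))
            sequences.append(seq)
            labels.append(c)
            ids.append(f"syn_c{c}_{j:05d}")
            if with_pssm:
                pssms.append(synthesize_pssm(
                    seq, profile, noise_sd=pssm_noise_sd,
                    seed=int(rng.integers(2 ** 31)), alpha=pssm_alpha))
    return SyntheticDataset(sequences=sequences,
                            labels=np.array(labels, dtype=int), ids=ids,
                            pssms=pssms if with_pssm else None, seed=seed)


def synthesize_pssm(sequence: str, profile: ClassProfile,
                    noise_sd: float = 1.0, seed: int = 0,
                    alpha: float = 0.6, scale: float = 2.0,
                    clip: int = 12) -> PSSMMatrix:
    """Integer log-odds profile consistent with the generating composition.

    Row i is ``round(scale * log2(p_i / background)) + noise`` clipped to
    [-clip, clip], where ``p_i`` mixes a point mass on the true residue
    at position i (weight ``alpha``) with the class composition.  Every
    row therefore carries class signal, and with ``alpha = 1`` and no
    noise the true residue's column attains the row maximum.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    idx = np.array([AMINO_ACIDS.index(ch) for ch in sequence])
    eps = 1e-4
    point = np.zeros((len(idx), 20))
    point[np.arange(len(idx)), idx] = 1.0
    p = alpha * point + (1.0 - alpha) * profile.composition + eps
    p /= p.sum(axis=1, keepdims=True)
    scores = np.round(scale * np.log2(p / BACKGROUND))
    if noise_sd > 0:
        scores += np.round(rng.normal(0.0, noise_sd, size=scores.shape))
    scores = np.clip(scores, -clip, clip)
    return PSSMMatrix(scores=scores, query=sequence)


def imbalanced_counts(total: int, k: int = 8,
                      pattern: Sequence[int] = TABLE1_TRAIN_COUNTS
                      ) -> List[int]:
    """Scale the benchmark-style imbalance pattern to ``total`` samples."""
    pattern = np.asarray(pattern[:k], dtype=float)
    counts = np.maximum(np.round(total * pattern / pattern.sum()), 1).astype(int)
    return counts.tolist()


def make_property_fixture(P: int, na_fraction: float, seed: int,
                          latent_rank: int = 3) -> str:
    """Emit an AAindex1-format property table with planted low-rank values.

    The 20 x P value matrix is a rank-``latent_rank`` product, so an
    autoencoder with a bottleneck of at least that rank can reconstruct
    it well.  ``round(na_fraction * P)`` indexes get one 'NA' cell and
    are expected to be screened out by the loader.
    """
    if P < 2:
        raise ValueError("need at least 2 property indexes")
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 3.0, size=(20, latent_rank))
    b = rng.normal(0.0, 1.0, size=(latent_rank, P))
    values = np.round(a @ b, 4)
    n_na = int(round(na_fraction * P))
    na_cols = rng.choice(P, size=n_na, replace=False)
    na_rows = rng.integers(0, 20, size=n_na)
    row1 = "ARNDCQEGHI"
    row2 = "LKMFPSTWYV"
    blocks = []
    for p in range(P):
        acc = f"SYNT{p:04d}"
        cells = {aa: f"{values[AMINO_ACIDS.index(aa), p]:.4f}"
                 for aa in AMINO_ACIDS}
        if p in na_cols:
            which = AMINO_ACIDS[na_rows[list(na_cols).index(p)]]
            cells[which] = "NA"
        header = "I    " + "     ".join(f"{x}/{y}" for x, y in zip(row1, row2))
        line1 = "  " + "  ".join(f"{cells[aa]:>9}" for aa in row1)
        line2 = "  " + "  ".join(f"{cells[aa]:>9}" for aa in row2)
        blocks.append(f"H {acc}\nD synthetic planted low-rank property index\n"
                      f"{header}\n{line1}\n{line2}\n//")
    return "\n".join(blocks) + "\n"


def emit_dataset(dataset: SyntheticDataset, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Write FASTA + label TSV (+ ASCII PSSMs and a manifest) to ``outdir``.

    The emitted files round-trip through the package's own readers, so
    the full command-line pipeline runs on synthetic output unchanged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": outdir / "sequences.fasta",
             "labels": outdir / "labels.tsv"}
    write_fasta(paths["fasta"], zip(dataset.ids, dataset.sequences))
    write_labels_tsv(paths["labels"],
                     dict(zip(dataset.ids, map(int, dataset.labels))))
    if dataset.pssms is not None:
        pssm_dir = outdir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        manifest = outdir / "pssm_manifest.tsv"
        with open(manifest, "w") as fh:
            for rid, pssm in zip(dataset.ids, dataset.pssms):
                p = pssm_dir / f"{rid}.pssm"
                write_ascii_pssm(p, pssm)
                fh.write(f"{rid}\tpssm/{rid}.pssm\n")
        paths["manifest"] = manifest
    return paths
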