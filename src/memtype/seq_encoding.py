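"""Fixed-length numeric encodings of protein sequences.

A protein sequence is mapped residue-by-residue to integer tokens
(alphabetical one-letter-code order, A=0 ... Y=19), cut or zero-padded
to a fixed length ``T`` (default 1500, chosen because sequences shorter
than 1500 residues dominate curated membrane-protein sets), and finally
expanded to a ``T x 20`` one-hot matrix or a ``T x d`` embedded matrix.
Positions beyond the true sequence end - and, under the default policy,
ambiguity codes such as ``X`` - contribute all-zero rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

#: the 20 standard amino acids, alphabetical by one-letter code
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: residue ambiguity / non-standard codes tolerated in real FASTA files
AMBIGUITY_CODES: str = "BZXUOJ"

#: sentinel token for padding and (by default) ambiguity codes
PAD_TOKEN: int = -1

#: default fixed length
DEFAULT_LENGTH: int = 1500


@dataclass(frozen=True)
class ResidueAlphabet:
    """Bijection between the 20 standard residues and token indices 0..19."""

    residues: str = AMINO_ACIDS
    pad_token: int = PAD_TOKEN

    def __post_init__(self):
        if len(self.residues) != 20 or len(set(self.residues)) != 20:
            raise ValueError("alphabet must contain exactly 20 distinct residues")
        if self.pad_token in range(20):
            raise ValueError("pad token must not collide with a residue index")

    @property
    def index_of(self) -> Dict[str, int]:
        return {aa: i for i, aa in enumerate(self.residues)}


DEFAULT_ALPHABET = ResidueAlphabet()


@dataclass
class EncodedSequence:
    """Tokens + mask + (optional) dense representation of one sequence."""

    tokens: np.ndarray          # (T,) int
    mask: np.ndarray            # (T,) bool, True where a real residue sits
    representation: np.ndarray | None = None   # (T, C) float

    def __post_init__(self):
        if self.tokens.shape != self.mask.shape:
            raise ValueError("tokens and mask must have the same length")


def encode_integer(sequence: str,
                   alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
                   ambiguous: str = "pad") -> np.ndarray:
    """Map a residue string to integer tokens (no padding applied).

    Parameters
    ----------
    sequence:
        Non-empty string of one-letter residue codes; ``*`` stop marks are
        stripped; case-insensitive.
    ambiguous:
        ``"pad"`` maps ambiguity codes (B, Z, X, U, O, J) to the pad token
        so they contribute zero rows downstream; ``"error"`` raises.
    """
    if ambiguous not in ("pad", "error"):
        raise ValueError("ambiguous policy must be 'pad' or 'error'")
    seq = sequence.strip().upper().replace("*", "")
    if not seq:
        raise ValueError("empty sequence")
    index = alphabet.index_of
    tokens = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        if ch in index:
            tokens[i] = index[ch]
        elif ch in AMBIGUITY_CODES:
            if ambiguous == "error":
                raise ValueError(f"ambiguous residue {ch!r} at position {i}")
            tokens[i] = alphabet.pad_token
        else:
            raise ValueError(f"invalid character {ch!r} at position {i}")
    return tokens


def pad_truncate(tokens: np.ndarray,
                 T: int = DEFAULT_LENGTH,
                 pad_token: int = PAD_TOKEN) -> Tuple[np.ndarray, np.ndarray]:
    """Cut to the N-terminal ``T`` tokens or zero-pad at the C-terminal end.

    Returns ``(tokens_T, mask)`` where ``mask`` is True wherever a real
    (non-pad) residue is present.  Idempotent: re-applying with the same
    ``T`` is the identity.
    """
    if T < 1:
        raise ValueError("fixed length T must be >= 1")
    tokens = np.asarray(tokens, dtype=np.int64)
    out = np.full(T, pad_token, dtype=np.int64)
    keep = min(len(tokens), T)
    out[:keep] = tokens[:keep]
    mask = out != pad_token
    return out, mask


def one_hot(tokens: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Expand tokens to a ``T x 20`` one-hot matrix; masked rows are zero."""
    tokens = np.asarray(tokens)
    mask = np.asarray(mask, dtype=bool)
    active = tokens[mask]
    if active.size and (active.min() < 0 or active.max() > 19):
        raise ValueError("tokens must lie in 0..19 where mask is true")
    out = np.zeros((len(tokens), 20))
    out[np.nonzero(mask)[0], active] = 1.0
    return out


def embed(tokens: np.ndarray, mask: np.ndarray,
          table: np.ndarray) -> np.ndarray:
    """Expand tokens to a ``T x d`` matrix of embedding rows.

    ``table`` is a ``20 x d`` matrix (row r = vector for residue token r).
    Masked positions give zero rows, mirroring one-hot zero padding.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 20:
        raise ValueError("embedding table must have exactly 20 rows")
    tokens = np.asarray(tokens)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros((len(tokens), table.shape[1]))
    idx = np.nonzero(mask)[0]
    out[idx] = table[tokens[idx]]
    return out


def encode_sequence(sequence: str,
                    T: int = DEFAULT_LENGTH,
                    table: np.ndarray | None = None,
                    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
                    ambiguous: str = "pad") -> EncodedSequence:
    """One-call pipeline: tokens -> pad/truncate -> one-hot or embedding."""
    tokens = encode_integer(sequence, alphabet, ambiguous)
    tokens, mask = pad_truncate(tokens, T, alphabet.pad_token)
    rep = one_hot(tokens, mask) if table is None else embed(tokens, mask, table)
    return EncodedSequence(tokens=tokens, mask=mask, representation=rep)


def encode_dataset(sequences: Sequence[str], T: int = DEFAULT_LENGTH,
                   table: np.ndarray | None = None,
                   ambiguous: str = "pad") -> np.ndarray:
    """Stack encoded representations into an ``N x T x C`` array."""
    return np.stack([encode_sequence(s, T=T, table=table,
                                     ambiguous=ambiguous).representation
                     for s in sequences])


# -- file interfaces --------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """Read a (possibly line-wrapped) multi-record FASTA.

    Stop codons (``*``) are stripped; returns ``(record_id, sequence)``
    pairs in file order.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).replace("*", "").upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: Union[str, Path],
                records: Iterable[Tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_labels_tsv(path: Union[str, Path]) -> Dict[str, int]:
    """Two-column TSV ``record_id<TAB>class`` with classes in 1..8."""
    labels: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            labels[parts[0]] = int(parts[1])
    return labels


def write_labels_tsv(path: Union[str, Path], labels: Dict[str, int]) -> None:
    with open(path, "w") as fh:
        for rid, lab in labels.items():
            fh.write(f"{rid}\t{lab}\n")
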