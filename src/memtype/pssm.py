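"""Position-specific scoring matrix (PSSM) parsing and shaping.

A PSSM is the L x 20 matrix of per-position log-odds scores produced by
iterative profile search (PSI-BLAST); entry ``M[i, j]`` scores residue
``j`` at sequence position ``i``.  This module reads the PSI-BLAST
``-out_ascii_pssm`` dialect (and a plain TSV fallback for synthetic
profiles), remaps columns to the package's canonical alphabetical
residue order, and pads/truncates to the fixed model length.  Scores
are used raw - no squashing or standardisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .seq_encoding import AMINO_ACIDS, DEFAULT_LENGTH

#: residue column order PSI-BLAST writes
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class PSSMMatrix:
    """L x 20 log-odds profile with its column order made explicit."""

    scores: np.ndarray                       # (L, 20) float
    residue_columns: str = AMINO_ACIDS
    query: Optional[str] = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM must have exactly 20 columns")
        if self.scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def reordered(self, order: str = AMINO_ACIDS) -> "PSSMMatrix":
        """Return a copy with columns permuted to ``order``."""
        perm = [self.residue_columns.index(aa) for aa in order]
        return PSSMMatrix(scores=self.scores[:, perm], residue_columns=order,
                          query=self.query)


def parse_ascii_pssm(source: Union[str, Path]) -> PSSMMatrix:
    """Parse PSI-BLAST ``-out_ascii_pssm`` text into a :class:`PSSMMatrix`.

    Only the first 20 numeric columns (log-odds) are kept; the 20
    percentage columns and the two per-position statistics are ignored.
    Columns are remapped to alphabetical residue order so the PSSM
    channel agrees with the sequence channel.  Raises ``ValueError``
    with a line number on malformed rows.
    """
    text = source if isinstance(source, str) and "\n" in source \
        else Path(source).read_text()
    lines = text.splitlines()
    header_order = None
    header_idx = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) == 40 and all(t in AMINO_ACIDS for t in toks):
            header_order = "".join(toks[:20])
            header_idx = i
            break
    if header_order is None:
        raise ValueError("no PSSM column-header line (40 residue letters) found")
    rows: List[List[float]] = []
    query: List[str] = []
    for lineno in range(header_idx + 1, len(lines)):
        line = lines[lineno]
        toks = line.split()
        if not toks:
            if rows:
                break          # blank line ends the body
            continue
        if not toks[0].lstrip("-").isdigit():
            break              # footer statistics (Lambda/K) reached
        if len(toks) != 44:
            raise ValueError(
                f"line {lineno + 1}: expected 44 fields "
                f"(index, residue, 20 scores, 20 percentages, 2 statistics), "
                f"got {len(toks)}")
        query.append(toks[1])
        rows.append([float(v) for v in toks[2:22]])
    if not rows:
        raise ValueError("PSSM body is empty")
    pssm = PSSMMatrix(scores=np.array(rows), residue_columns=header_order,
                      query="".join(query))
    return pssm.reordered(AMINO_ACIDS)


def write_ascii_pssm(path: Union[str, Path], pssm: PSSMMatrix) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (for fixtures/synthetic data).

    Percentage columns are filled with zeros and the two trailing
    statistics with a constant, which the parser ignores by contract.
    """
    mat = pssm.reordered(PSIBLAST_ORDER)
    query = mat.query or "A" * mat.length
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per position, "
                 "and relative weight of gapless real matches to pseudocounts\n")
        fh.write(" " * 11 + "  ".join(PSIBLAST_ORDER) + "   "
                 + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, row in enumerate(mat.scores, 1):
            scores = " ".join(f"{int(round(v)):3d}" for v in row)
            pcts = " ".join("  0" for _ in range(20))
            fh.write(f"{i:5d} {query[i - 1]}  {scores}  {pcts}  0.00 0.00\n")
        fh.write("\n")


def parse_pssm_tsv(source: Union[str, Path]) -> PSSMMatrix:
    """Plain L x 20 TSV fallback; optional header row of residue letters."""
    text = source if isinstance(source, str) and ("\n" in source or "\t" in source) \
        else Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    order = AMINO_ACIDS
    start = 0
    first = lines[0].split("\t")
    if all(t in AMINO_ACIDS for t in first) and len(first) == 20:
        order = "".join(first)
        start = 1
    rows = []
    for lineno, ln in enumerate(lines[start:], start + 1):
        parts = ln.split("\t")
        if len(parts) != 20:
            raise ValueError(f"line {lineno}: expected 20 columns, got {len(parts)}")
        rows.append([float(p) for p in parts])
    return PSSMMatrix(scores=np.array(rows), residue_columns=order).reordered()


def pad_truncate_pssm(pssm: PSSMMatrix,
                      T: int = DEFAULT_LENGTH) -> Tuple[np.ndarray, np.ndarray]:
    """Fix the profile to ``T`` rows: keep the first ``T`` or zero-pad.

    Returns ``(matrix, mask)`` with ``matrix`` of shape (T, 20); the mask
    marks rows holding real profile positions.  Retained scores are
    never altered.
    """
    if T < 1:
        raise ValueError("fixed length T must be >= 1")
    mat = pssm.reordered(AMINO_ACIDS).scores
    out = np.zeros((T, 20))
    keep = min(mat.shape[0], T)
    out[:keep] = mat[:keep]
    mask = np.zeros(T, dtype=bool)
    mask[:keep] = True
    return out, mask


def read_pssm_manifest(path: Union[str, Path]) -> Dict[str, Path]:
    """TSV manifest ``record_id<TAB>pssm_path`` (paths relative to the manifest)."""
    base = Path(path).parent
    manifest: Dict[str, Path] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            p = Path(parts[1])
            manifest[parts[0]] = p if p.is_absolute() else base / p
    return manifest


def load_pssm_dataset(manifest: Dict[str, Path], ids: List[str],
                      T: int = DEFAULT_LENGTH) -> np.ndarray:
    """Stack padded profiles for ``ids`` into an ``N x T x 20`` array."""
    mats = []
    for rid in ids:
        path = manifest[rid]
        text = Path(path).read_text()
        if "\t" in text.splitlines()[0] if text.splitlines() else False:
            pssm = parse_pssm_tsv(text)
        else:
            try:
                pssm = parse_ascii_pssm(text)
            except ValueError:
                pssm = parse_pssm_tsv(text)
        mats.append(pad_truncate_pssm(pssm, T)[0])
    return np.stack(mats)
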