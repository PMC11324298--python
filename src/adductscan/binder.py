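"""PSSM-based binder prediction.

A position-specific scoring matrix (PSSM) of per-position log2-odds stands in
for an external neural-network predictor: peptides are scored additively, and
a peptide's percentile rank against a large random background defines "strong
binders" (small rank = strong), the same rank convention the field's
predictors print.  Binary binder calls come from IC50 (binders <= 500 nM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import AMINO_ACIDS

__all__ = [
    "PSSM",
    "EpitopeRecord",
    "background_scores",
    "classify_binder",
    "is_strong_binder",
    "percentile_rank",
    "pssm_from_epitopes",
    "read_epitopes_tsv",
    "score_peptide",
    "write_epitopes_tsv",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_FLOOR = -20.0  # log2-odds floor for zero-frequency cells


@dataclass(frozen=True)
class PSSM:
    """Log2-odds matrix of shape (length, 20) over the canonical alphabet."""

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05))
    pseudocount: float = 1.0
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 20:
            raise ValueError(f"matrix must be (length, 20), got {mat.shape}")
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 20 frequencies summing to 1")
        mat.setflags(write=False)
        bg.setflags(write=False)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "background", bg)
        # Columns without floored cells must invert to a frequency simplex.
        freqs = self.implied_frequencies()
        unfloored = ~np.any(mat <= self.floor + 1e-12, axis=1)
        if unfloored.any():
            sums = freqs[unfloored].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("PSSM columns do not invert to frequencies")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def implied_frequencies(self) -> np.ndarray:
        """Invert log-odds against the background: f = 2**entry * background."""
        return (2.0 ** self.matrix) * self.background[None, :]

    @classmethod
    def from_frequencies(cls, freqs: np.ndarray,
                         background: np.ndarray | None = None,
                         floor: float = DEFAULT_FLOOR) -> "PSSM":
        freqs = np.asarray(freqs, dtype=float)
        bg = np.full(20, 0.05) if background is None else np.asarray(background)
        with np.errstate(divide="ignore"):
            mat = np.log2(freqs / bg[None, :])
        return cls(np.maximum(mat, floor), background=bg, pseudocount=0.0,
                   floor=floor)

    def entry(self, pos: int, aa: str) -> float:
        """Log2-odds of residue ``aa`` at 1-based position ``pos``."""
        return float(self.matrix[pos - 1, _AA_INDEX[aa]])

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))

    def write(self, path: str | Path) -> None:
        """Serialize as a square-matrix text file with a residue header row."""
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, row in enumerate(self.matrix, start=1):
                fh.write(str(i) + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PSSM":
        df = pd.read_csv(path, sep="\t")
        header = list(df.columns[1:])
        if header != list(AMINO_ACIDS):
            raise ValueError("PSSM header row must list the 20 canonical residues")
        return cls(df[header].to_numpy(dtype=float))


@dataclass(frozen=True)
class EpitopeRecord:
    """One epitope with (optionally) a measured IC50 in nM."""

    sequence: str
    ic50_nm: float | None
    allele: str

    def __post_init__(self) -> None:
        if self.ic50_nm is not None and self.ic50_nm <= 0:
            raise ValueError(f"ic50_nm must be positive, got {self.ic50_nm}")


def classify_binder(record: EpitopeRecord, threshold_nm: float = 500.0) -> str:
    """"binder" iff IC50 <= threshold (inclusive), else "nonbinder"."""
    if record.ic50_nm is None:
        raise ValueError(f"record {record.sequence} has no IC50 measurement")
    return "binder" if record.ic50_nm <= threshold_nm else "nonbinder"


def pssm_from_epitopes(
    sequences: Sequence[str],
    alpha: float = 1.0,
    background: np.ndarray | None = None,
    floor: float = DEFAULT_FLOOR,
) -> PSSM:
    """Estimate a PSSM from equal-length binder sequences.

    Column frequency = (count + alpha) / (n + 20 * alpha); entries are
    log2(frequency / background), floored for zero-frequency cells as
    alpha -> 0.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must all have equal length")
    counts = np.zeros((length, 20))
    for s in sequences:
        for i, aa in enumerate(s):
            counts[i, _AA_INDEX[aa]] += 1
    n = len(sequences)
    freqs = (counts + alpha) / (n + 20.0 * alpha)
    bg = np.full(20, 0.05) if background is None else np.asarray(background, float)
    with np.errstate(divide="ignore"):
        mat = np.log2(freqs / bg[None, :])
    return PSSM(np.maximum(mat, floor), background=bg, pseudocount=alpha,
                floor=floor)


def score_peptide(sequence: str, pssm: PSSM) -> float:
    """Additive log2-odds score: sum over positions of matrix[i, aa_i]."""
    if len(sequence) != pssm.length:
        raise ValueError(
            f"peptide length {len(sequence)} does not match PSSM length "
            f"{pssm.length}")
    idx = [_AA_INDEX[aa] for aa in sequence]
    return float(pssm.matrix[np.arange(pssm.length), idx].sum())


def background_scores(
    pssm: PSSM,
    n: int = 100_000,
    rng: np.random.Generator | None = None,
    composition: np.ndarray | None = None,
) -> np.ndarray:
    """Scores of ``n`` i.i.d. random peptides of matching length.

    Uniform residue composition by default; pass a 20-vector to use a
    different background composition.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if composition is None:
        idx = rng.integers(0, 20, size=(n, pssm.length))
    else:
        comp = np.asarray(composition, float)
        idx = rng.choice(20, size=(n, pssm.length), p=comp / comp.sum())
    return pssm.matrix[np.arange(pssm.length)[None, :], idx].sum(axis=1)


def percentile_rank(score: float, background: np.ndarray) -> float:
    """Percent of background scores >= ``score`` (0 = better than all)."""
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background score distribution is empty")
    return 100.0 * np.count_nonzero(bg >= score) / bg.size


def is_strong_binder(rank: float, threshold: float = 0.5) -> bool:
    """Strong binder iff percentile rank <= threshold (default 0.5)."""
    return rank <= threshold


def read_epitopes_tsv(path: str | Path) -> list[EpitopeRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        ic50 = row.get("ic50_nm")
        ic50 = None if pd.isna(ic50) else float(ic50)
        out.append(EpitopeRecord(str(row["sequence"]), ic50, str(row["allele"])))
    return out


def write_epitopes_tsv(records: Iterable[EpitopeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tic50_nm\tallele\n")
        for r in records:
            ic50 = "" if r.ic50_nm is None else f"{r.ic50_nm:.6g}"
            fh.write(f"{r.sequence}\t{ic50}\t{r.allele}\n")
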