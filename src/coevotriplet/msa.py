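"""Alignment handling: parsing, encoding, sequence weights, Neff, frequencies.

The statistical backbone of coevolution analysis lives here. Sequences are
down-weighted by redundancy at an identity threshold (default 0.8): sequence
n gets weight 1/(1 + number of other sequences at >= 80% identity), and the
effective alignment depth is

    Neff = (1/L) * sum_n w_n

so duplicating a sequence never changes Neff. Single-site frequencies
f_i(a) and pair frequencies f_ij(a,b) are computed with arbitrary
nonnegative sequence weights and feed the covariance / precision / Potts
feature extractors in :mod:`coevotriplet.coevolution`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

from coevotriplet.alphabet import ALPHABET, GAP_CODE, N_STATES, decode, encode, one_hot

__all__ = [
    "Alignment",
    "WeightedStats",
    "read_alignment",
    "write_fasta",
    "pairwise_identity",
    "identity_matrix",
    "compute_weights_and_neff",
    "compute_frequencies",
    "needs_deeper_search",
]


@dataclass
class Alignment:
    """An integer-encoded multiple sequence alignment.

    ``sequences`` is an (N, L) int8 matrix of codes in [0, 20] over the
    21-letter alphabet (gap = 20). Row ``query_index`` holds the query.
    """

    sequences: np.ndarray
    ids: list[str] = field(default_factory=list)
    query_index: int = 0
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be a 2-D (N, L) matrix")
        n, length = self.sequences.shape
        if n < 1 or length < 1:
            raise ValueError("alignment must have N >= 1 sequences and L >= 1 columns")
        if self.sequences.min() < 0 or self.sequences.max() > GAP_CODE:
            raise ValueError("sequence codes must lie in [0, 20]")
        if not 0 <= self.query_index < n:
            raise ValueError("query_index out of range")
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids length must match number of sequences")

    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    @property
    def query(self) -> np.ndarray:
        return self.sequences[self.query_index]

    def one_hot(self, dtype=np.float64) -> np.ndarray:
        """(N, L, 21) one-hot view of the alignment."""
        return one_hot(self.sequences, dtype=dtype)

    @classmethod
    def from_strings(cls, seqs: Sequence[str], ids: Iterable[str] | None = None,
                     query_index: int = 0) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        mat = np.stack([encode(s) for s in seqs])
        return cls(mat, ids=list(ids) if ids is not None else [], query_index=query_index)


@dataclass
class WeightedStats:
    """Sequence weights, Neff, and (weighted) site/pair frequencies."""

    weights: np.ndarray
    neff: float
    f1: np.ndarray | None = None      # (L, 21)
    f2: np.ndarray | None = None      # (L, L, 21, 21)
    identity_threshold: float = 0.8


def _project_a3m(raw: str) -> str:
    """Drop A3M insertion states: lowercase letters and '.' columns."""
    return "".join(c for c in raw if not (c.islower() or c == "."))


def read_alignment(path: str | Path, format: Literal["fasta", "a3m"] | None = None) -> Alignment:
    """Read a FASTA or A3M alignment into an :class:`Alignment`.

    For A3M, lowercase residues are insertion states relative to the query
    and are removed, leaving match-state columns only; ``.`` is dropped the
    same way. Non-standard residues (B, J, O, U, X, Z) encode to the gap
    state. The first record is taken as the query.
    """
    path = Path(path)
    if format is None:
        format = "a3m" if path.suffix.lower() in {".a3m"} else "fasta"
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    seqs = [str(r.seq) for r in records]
    ids = [r.id for r in records]
    if format == "a3m":
        seqs = [_project_a3m(s) for s in seqs]
    if len(seqs[0]) == 0:
        raise ValueError("zero-length query sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"ragged alignment after {'A3M projection' if format == 'a3m' else 'parsing'}: "
            f"lengths {sorted(lengths)}")
    return Alignment.from_strings(seqs, ids=ids)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Round-trip an encoded alignment back to plain FASTA."""
    with open(path, "w") as fh:
        for name, row in zip(aln.ids, aln.sequences):
            fh.write(f">{name}\n{decode(row)}\n")


def pairwise_identity(a: np.ndarray, b: np.ndarray, *,
                      denominator: Literal["full", "nongap"] = "full",
                      gap_gap_match: bool = True) -> float:
    """Fraction of identical positions between two encoded sequences.

    Default convention: the denominator is the full alignment length and a
    gap aligned to a gap counts as a match. The alternative reading
    (non-gap columns only) is available behind the ``denominator`` switch.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sequences must be 1-D and of equal length")
    same = a == b
    if not gap_gap_match:
        same &= ~((a == GAP_CODE) & (b == GAP_CODE))
    if denominator == "full":
        denom = a.size
    else:
        valid = (a != GAP_CODE) | (b != GAP_CODE)
        denom = int(valid.sum())
        same = same & valid
    if denom == 0:
        return 0.0
    return float(same.sum()) / denom


def identity_matrix(aln: Alignment) -> np.ndarray:
    """All-pairs identity S_{m,n} (full-length denominator, gap=gap matches).

    Uses a one-hot inner product, so cost is one (N, 21L) x (21L, N) matmul.
    """
    x = aln.one_hot(dtype=np.float32).reshape(aln.n_sequences, -1)
    counts = x @ x.T
    return counts / float(aln.length)


def compute_weights_and_neff(aln: Alignment, threshold: float = 0.8) -> WeightedStats:
    """Redundancy weights and the effective sequence number.

    w_n = 1 / (1 + #{m != n : S_mn >= threshold});  Neff = (1/L) sum_n w_n.
    """
    if not 0 < threshold:
        raise ValueError("identity threshold must be positive")
    sim = identity_matrix(aln) >= threshold
    np.fill_diagonal(sim, False)
    n_similar = sim.sum(axis=1)
    weights = 1.0 / (1.0 + n_similar.astype(np.float64))
    neff = float(weights.sum() / aln.length)
    return WeightedStats(weights=weights, neff=neff, identity_threshold=threshold)


def compute_frequencies(aln: Alignment, weights: np.ndarray | None = None,
                        pseudocount: float = 0.0) -> WeightedStats:
    """Weighted single-site and pair frequencies.

    f1[i, a] = sum_n w_n 1[x_ni = a] / sum_n w_n, and f2 analogously over
    position pairs; with ``pseudocount`` lambda, f <- (1-lambda) f +
    lambda * uniform (uniform over 21 states / 441 state pairs).
    """
    n, length = aln.sequences.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (n,):
        raise ValueError("weights must have one entry per sequence")
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be nonnegative and not all zero")
    wsum = weights.sum()
    x = aln.one_hot(dtype=np.float64).reshape(n, length * N_STATES)
    xw = x * weights[:, None]
    f1 = (xw.sum(axis=0) / wsum).reshape(length, N_STATES)
    f2 = (xw.T @ x) / wsum
    f2 = f2.reshape(length, N_STATES, length, N_STATES).transpose(0, 2, 1, 3)
    if pseudocount > 0:
        lam = float(pseudocount)
        f1 = (1 - lam) * f1 + lam / N_STATES
        f2 = (1 - lam) * f2 + lam / (N_STATES * N_STATES)
        # same-column blocks must stay the diagonal embedding of f1
        for i in range(length):
            f2[i, i] = np.diag(f1[i])
    neff = float(weights.sum() / length)
    return WeightedStats(weights=weights, neff=neff, f1=f1, f2=f2)


def needs_deeper_search(neff: float, threshold: float = 128.0) -> bool:
    """Decision predicate of the staged alignment-search protocol.

    True iff Neff is strictly below the trigger (default 128), i.e. the
    current alignment is too shallow and the next, more sensitive search
    stage should run. The searches themselves are external to this package.
    """
    if neff < 0:
        raise ValueError("neff must be nonnegative")
    return neff < threshold
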