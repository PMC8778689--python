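"""Percent-identity statistics from global alignments (p-distance method).

Identity between two sequences is computed as 100 * identical / compared
over the columns of a global pairwise alignment, with *pairwise deletion*:
any column containing a gap is excluded from both counts. This is the
p-distance convention of the standard molecular-evolution toolkits, and the
statistic used throughout virus species demarcation work.

Matrices report values rounded to one decimal place, the precision at which
such identities are conventionally published.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import Alignment, Scoring, default_scoring, global_align, GAP
from .seqio import SequenceRecord

__all__ = [
    "IdentityStats",
    "IdentityMatrix",
    "p_distance_identity",
    "pairwise_identity",
    "identity_matrix",
    "range_summary",
]


@dataclass
class IdentityStats:
    """Identity over the gap-free columns of an alignment."""

    n_compared: int
    n_identical: int

    def __post_init__(self) -> None:
        if self.n_identical > self.n_compared:
            raise ValueError("n_identical cannot exceed n_compared")

    @property
    def defined(self) -> bool:
        return self.n_compared > 0

    @property
    def pct_identity(self) -> float | None:
        """Percent identity, or None when no sites are comparable."""
        if not self.defined:
            return None
        return 100.0 * self.n_identical / self.n_compared


def p_distance_identity(aln: Alignment) -> IdentityStats:
    """Identity of an alignment under pairwise deletion of gapped columns."""
    compared = 0
    identical = 0
    for x, y in zip(aln.a_aligned, aln.b_aligned):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x == y:
            identical += 1
    return IdentityStats(n_compared=compared, n_identical=identical)


def pairwise_identity(a: str, b: str, alphabet: str = "nucleotide",
                      scoring: Scoring | None = None) -> IdentityStats:
    """Align two raw sequences and return their p-distance identity."""
    return p_distance_identity(global_align(a, b, alphabet, scoring))


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with diagonal fixed at 100."""

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def identity_matrix(seqs: list[SequenceRecord], alphabet: str = "nucleotide",
                    scoring: Scoring | None = None,
                    trim: tuple[int, int] | None = None) -> IdentityMatrix:
    """All-pairs p-distance identity matrix.

    ``trim=(start, end)`` (1-based, inclusive) extracts a shared coordinate
    range from every sequence before alignment, the way published identity
    tables restrict to a common amplicon region. Duplicate ids are an error.
    """
    if len(seqs) < 2:
        raise ValueError("identity matrix needs at least 2 sequences")
    labels = [s.id for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids in identity matrix input")
    if scoring is None:
        scoring = default_scoring(alphabet)
    residues = [s.residues for s in seqs]
    if trim is not None:
        start, end = trim
        if start < 1 or end < start:
            raise ValueError(f"bad trim range {trim}")
        residues = [r[start - 1 : end] for r in residues]
    k = len(seqs)
    values = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            stats = pairwise_identity(residues[i], residues[j], alphabet, scoring)
            pct = stats.pct_identity
            if pct is None:
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            values[i, j] = values[j, i] = round(pct, 1)
    return IdentityMatrix(labels=labels, values=values)


def range_summary(m: IdentityMatrix) -> tuple[float, float]:
    """(min, max) percent identity over the off-diagonal entries."""
    if len(m.labels) < 2:
        raise ValueError("range summary needs at least 2 labels")
    off = m.off_diagonal()
    return float(off.min()), float(off.max())
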