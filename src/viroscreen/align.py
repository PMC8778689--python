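"""Global pairwise alignment with affine gap penalties.

A Needleman-Wunsch / Gotoh aligner used by the identity analysis. The
implementation is deliberately explicit about two contracts that matter for
reproducible identity statistics:

* gap cost model: a gap of length ``g`` costs ``gap_open + (g - 1) * gap_extend``
  (the opening column carries the open penalty, every further gapped column
  the extension penalty); gap states open only from the match state, so a
  deletion directly following an insertion is not representable — under the
  shipped scoring schemes such alignments are never optimal anyway;
* deterministic traceback: on score ties the diagonal (substitution) move is
  preferred, then the vertical move (gap in the second sequence), then the
  horizontal move (gap in the first sequence).

Default scoring: nucleotide match +2 / mismatch -3 with stiff gap penalties
(open -12 / extend -6, in the tradition of the DNA defaults of the classic
multiple-alignment tools), and protein BLOSUM62 with gap open -11 /
extend -1. The stiff nucleotide gap penalties matter for identity
statistics: with soft penalties the aligner bridges mismatch clusters in
divergent pairs with spurious compensating gaps, and since gapped columns
are excluded from the p-distance, apparent identity is inflated by several
points below ~80% identity. With the stiff defaults, substitution-only
variants align gap-free and planted identities are recovered to within a
small fraction of a point across the 70-99% range.

The dynamic program is vectorised row-wise with numpy; the three state
matrices are kept (float32) for the traceback, so memory grows as
``3 * len(a) * len(b)`` cells — comfortable for the fragment-scale sequences
this package compares (up to a few kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

__all__ = ["Scoring", "Alignment", "global_align", "NT_SCORING", "PROTEIN_SCORING"]

NEG = np.float32(-1e9)
GAP = "-"


@dataclass(frozen=True)
class Scoring:
    """Scoring descriptor for :func:`global_align`.

    Either ``match``/``mismatch`` (simple alphabet-agnostic scheme) or
    ``matrix_name`` (a Biopython substitution matrix, e.g. BLOSUM62) is used.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -12.0
    gap_extend: float = -6.0
    matrix_name: str | None = None

    def describe(self) -> str:
        sub = self.matrix_name or f"match {self.match:+g}/mismatch {self.mismatch:+g}"
        return f"{sub}, gap open {self.gap_open:+g}, extend {self.gap_extend:+g}"


NT_SCORING = Scoring(match=2, mismatch=-3, gap_open=-12, gap_extend=-6)
PROTEIN_SCORING = Scoring(gap_open=-11, gap_extend=-1, matrix_name="BLOSUM62")


def default_scoring(alphabet: str) -> Scoring:
    if alphabet in ("nucleotide", "nt"):
        return NT_SCORING
    if alphabet in ("protein", "aa"):
        return PROTEIN_SCORING
    raise ValueError(f"unknown alphabet {alphabet!r}")


@dataclass
class Alignment:
    """A global pairwise alignment; removing gaps recovers the two inputs."""

    a_aligned: str
    b_aligned: str
    score: float
    params: str

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned strings must have equal length")


@lru_cache(maxsize=4)
def _blosum(name: str):
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    lut = {}
    for i, x in enumerate(alphabet):
        for j, y in enumerate(alphabet):
            lut[(x, y)] = float(mat[i, j])
    return alphabet, lut


def _substitution_scores(a: str, b: str, scoring: Scoring) -> np.ndarray:
    """(len(a), len(b)) matrix of substitution scores."""
    if scoring.matrix_name is None:
        av = np.frombuffer(a.encode(), dtype=np.uint8)
        bv = np.frombuffer(b.encode(), dtype=np.uint8)
        eq = av[:, None] == bv[None, :]
        return np.where(eq, np.float32(scoring.match), np.float32(scoring.mismatch))
    alphabet, lut = _blosum(scoring.matrix_name)
    # residues outside the matrix alphabet are scored as X
    fallback = "X" if "X" in alphabet else alphabet[-1]
    a_norm = [c if c in alphabet else fallback for c in a]
    b_norm = [c if c in alphabet else fallback for c in b]
    out = np.empty((len(a), len(b)), dtype=np.float32)
    for i, x in enumerate(a_norm):
        for j, y in enumerate(b_norm):
            out[i, j] = lut[(x, y)]
    return out


def global_align(a: str, b: str, alphabet: str = "nucleotide",
                 scoring: Scoring | None = None) -> Alignment:
    """Optimal global alignment of ``a`` and ``b`` under affine gap penalties.

    Raises ``ValueError`` on an empty input sequence. The traceback is
    deterministic: ties prefer diagonal, then up (gap in ``b``), then left
    (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if scoring is None:
        scoring = default_scoring(alphabet)
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    go = np.float32(scoring.gap_open)
    ge = np.float32(scoring.gap_extend)
    sub = _substitution_scores(a, b, scoring)

    M = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in b (vertical)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in a (horizontal)
    M[0, 0] = 0.0
    if m:
        Iy[0, 1:] = go + ge * np.arange(m, dtype=np.float32)
    if n:
        Ix[1:, 0] = go + ge * np.arange(n, dtype=np.float32)

    js = np.arange(1, m + 1, dtype=np.float32)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub[i - 1] + prev_best[:-1]
        Ix[i] = np.maximum(M[i - 1] + go, Ix[i - 1] + ge)
        Ix[i, 0] = go + ge * np.float32(i - 1)
        M[i, 0] = NEG
        # horizontal gap state: running-max scan along the row
        d = M[i, :-1] + go - ge * js
        Iy[i, 1:] = ge * js + np.maximum.accumulate(d)
        Iy[i, 0] = NEG

    # traceback; states: 0 = M (diagonal), 1 = Ix (up), 2 = Iy (left)
    tol = np.float32(1e-3)
    i, j = n, m
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    best = max(finals)
    state = min(s for s in range(3) if finals[s] >= best - tol)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            cands = (M[i, j], Ix[i, j], Iy[i, j])
            state = min(s for s in range(3) if abs(cands[s] - target) <= tol)
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            target = Ix[i, j]
            i -= 1
            if abs(M[i, j] + go - target) <= tol:
                state = 0
            else:
                state = 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            target = Iy[i, j]
            j -= 1
            if abs(M[i, j] + go - target) <= tol:
                state = 0
            else:
                state = 2
    return Alignment(
        a_aligned="".join(reversed(out_a)),
        b_aligned="".join(reversed(out_b)),
        score=float(best),
        params=scoring.describe(),
    )
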