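"""Orientation-aware read assignment via exact k-mer matching.

The replication-intermediate screen needs, per contig, how many reads map in
sense versus antisense orientation. This module provides a deliberately
simple, fully specified stand-in for a general-purpose read mapper:

* every k-mer of every contig is indexed on both strands (a k-mer and its
  reverse complement point at opposite strands of the same contig);
* a read is assigned to the (contig, strand) pair matching the largest
  fraction of its k-mers, provided that fraction reaches ``min_frac`` and
  strictly exceeds the runner-up; exact ties are ambiguous, weak matches are
  unassigned;
* k-mer matching itself tolerates no mismatches — tolerance comes from
  requiring only a fraction of the read's k-mers to match.

Ambiguous reads are excluded from both strand counts, keeping the
antisense/sense ratio statistic well defined. With an odd k no k-mer is its
own reverse complement; palindromic (even-k) k-mers are indexed on both
strands and can therefore never decide orientation on their own.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .seqio import ReadRecord, SequenceRecord, reverse_complement

__all__ = [
    "KmerIndex",
    "Assignment",
    "ContigCounts",
    "StrandCounts",
    "build_index",
    "assign_read",
    "count_strands",
    "write_counts",
    "read_counts",
]

TOTAL_ROW = "*"  # label of the totals row in counts TSVs


@dataclass
class KmerIndex:
    k: int
    entries: dict = field(default_factory=dict)  # k-mer -> frozenset of (contig_id, strand)
    contig_ids: tuple = ()


def build_index(contigs: Iterable[SequenceRecord], k: int = 21) -> KmerIndex:
    """Index every k-mer of every contig on both strands.

    Default k=21: long enough that random 4^21 collisions are negligible at
    desk scale, short enough to leave many k-mers per 100 nt read.
    """
    if k < 1:
        raise ValueError("k must be positive")
    entries: dict[str, set] = {}
    ids = []
    for contig in contigs:
        if not isinstance(contig, SequenceRecord) or contig.alphabet != "nucleotide":
            raise TypeError(f"contig {getattr(contig, 'id', contig)!r} is not a nucleotide record")
        ids.append(contig.id)
        s = contig.residues
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            entries.setdefault(km, set()).add((contig.id, "+"))
            entries.setdefault(reverse_complement(km), set()).add((contig.id, "-"))
    return KmerIndex(
        k=k,
        entries={km: frozenset(v) for km, v in entries.items()},
        contig_ids=tuple(ids),
    )


@dataclass
class Assignment:
    status: str  # "assigned" | "ambiguous" | "unassigned"
    contig_id: Optional[str] = None
    strand: Optional[str] = None


def assign_read(index: KmerIndex, read: ReadRecord, min_frac: float = 0.5) -> Assignment:
    """Assign a read to the (contig, strand) matching most of its k-mers."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    k = index.k
    n = len(read.residues) - k + 1
    if n < 1:
        warnings.warn(f"read {read.id} shorter than k={k}; unassigned", stacklevel=2)
        return Assignment(status="unassigned")
    votes: Counter = Counter()
    seq = read.residues
    for i in range(n):
        for target in index.entries.get(seq[i : i + k], ()):
            votes[target] += 1
    if not votes:
        return Assignment(status="unassigned")
    best_count = max(votes.values())
    if best_count / n < min_frac:
        return Assignment(status="unassigned")
    leaders = [t for t, c in votes.items() if c == best_count]
    if len(leaders) > 1:
        return Assignment(status="ambiguous")
    contig_id, strand = leaders[0]
    return Assignment(status="assigned", contig_id=contig_id, strand=strand)


@dataclass
class ContigCounts:
    n_sense: int = 0      # reads assigned to the + strand of the stored contig
    n_antisense: int = 0  # reads assigned to the - strand


@dataclass
class StrandCounts:
    """Per-contig strand tallies plus pipeline-level leftovers.

    Conservation: assigned + ambiguous + unassigned == total input reads.
    When reads carry ground-truth strand tags, a confusion summary
    (n_truth, n_correct) over assigned reads is kept.
    """

    per_contig: dict = field(default_factory=dict)  # contig_id -> ContigCounts
    n_ambiguous: int = 0
    n_unassigned: int = 0
    total_reads: int = 0
    n_truth: int = 0
    n_correct: int = 0

    def get(self, contig_id: str) -> ContigCounts:
        return self.per_contig.get(contig_id, ContigCounts())

    @property
    def n_assigned(self) -> int:
        return sum(c.n_sense + c.n_antisense for c in self.per_contig.values())

    @property
    def truth_accuracy(self) -> Optional[float]:
        if not self.n_truth:
            return None
        return self.n_correct / self.n_truth


def count_strands(index: KmerIndex, reads: Iterable[ReadRecord],
                  min_frac: float = 0.5) -> StrandCounts:
    """Tally :func:`assign_read` over all reads.

    A read generated from the + strand of its contig ("sense" truth tag)
    should be assigned strand "+"; the confusion summary counts how often
    assigned reads agree with their truth tag.
    """
    counts = StrandCounts(per_contig={cid: ContigCounts() for cid in index.contig_ids})
    for read in reads:
        counts.total_reads += 1
        a = assign_read(index, read, min_frac)
        if a.status == "unassigned":
            counts.n_unassigned += 1
            continue
        if a.status == "ambiguous":
            counts.n_ambiguous += 1
            continue
        cc = counts.per_contig.setdefault(a.contig_id, ContigCounts())
        if a.strand == "+":
            cc.n_sense += 1
        else:
            cc.n_antisense += 1
        if read.truth_strand is not None:
            counts.n_truth += 1
            expected = "+" if read.truth_strand == "sense" else "-"
            if a.strand == expected:
                counts.n_correct += 1
    return counts


def write_counts(counts: StrandCounts, path) -> None:
    """TSV: one row per contig; a final '*' row carries the pipeline totals."""
    rows = [
        {"contig_id": cid, "n_sense": c.n_sense, "n_antisense": c.n_antisense,
         "n_ambiguous": 0, "n_unassigned": 0}
        for cid, c in sorted(counts.per_contig.items())
    ]
    rows.append(
        {"contig_id": TOTAL_ROW, "n_sense": 0, "n_antisense": 0,
         "n_ambiguous": counts.n_ambiguous, "n_unassigned": counts.n_unassigned}
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts(path) -> StrandCounts:
    df = pd.read_csv(path, sep="\t")
    counts = StrandCounts()
    for row in df.itertuples(index=False):
        if row.contig_id == TOTAL_ROW:
            counts.n_ambiguous = int(row.n_ambiguous)
            counts.n_unassigned = int(row.n_unassigned)
            continue
        counts.per_contig[str(row.contig_id)] = ContigCounts(
            n_sense=int(row.n_sense), n_antisense=int(row.n_antisense)
        )
    counts.total_reads = (
        counts.n_assigned + counts.n_ambiguous + counts.n_unassigned
    )
    return counts
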