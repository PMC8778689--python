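"""The ORFan replication-signature screen.

A contig with no detectable homology ("ORFan") is a candidate replicating
viral RNA when it looks like a coding RNA being copied through a
double-stranded intermediate:

1. homology exclusion — contigs with any hit at E-value <= cutoff are
   discarded (known genes and known viruses leave the pool);
2. size — contig longer than 1 kb;
3. coding — longest ORF of at least 150 aa (~15 kDa);
4. replication signature — reads map to *both* strands, and the
   antisense/sense read ratio reaches a floor (default 1/10).

Strand polarity is defined by the contig's longest ORF (sense = coding
strand), because assembler output orientation is arbitrary; the verdict is
therefore invariant under reverse-complementing the contig. Ratios above 1
(antisense-dominant) also pass: the floor is a lower bound only.

An optional per-contig ``dna_positive`` annotation mirrors the downstream
wet-lab verdict (real-time PCR on total nucleic acid versus cDNA): a
DNA-positive ORFan is flagged as genomic in origin and excluded from the
viral pool even when the sequence filter passed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .annotate import find_orfs
from .mapping import StrandCounts
from .seqio import HitRecord, SequenceRecord

__all__ = ["OrfanParams", "OrfanVerdict", "remove_homologous", "evaluate_orfan", "screen"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrfanParams:
    min_contig_len: int = 1000      # nt; "over 1 kb" read strictly
    min_protein_len: int = 150      # aa, stop excluded
    min_strand_ratio: float = 0.1   # antisense/sense floor
    evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        if self.min_contig_len <= 0 or self.min_protein_len <= 0:
            raise ValueError("length thresholds must be positive")
        if not 0 < self.min_strand_ratio <= 1:
            raise ValueError("min_strand_ratio must be in (0, 1]")


@dataclass
class OrfanVerdict:
    contig_id: str
    has_homology: bool
    len_ok: bool
    orf_ok: bool
    both_strands_ok: bool
    ratio_ok: bool
    antisense_ratio: Optional[float]  # None when the sense count is 0
    longest_orf_len: int              # aa
    passed: bool
    genomic_origin: Optional[bool] = None  # dna_positive annotation, when known

    def __post_init__(self) -> None:
        expected = (
            not self.has_homology and self.len_ok and self.orf_ok
            and self.both_strands_ok and self.ratio_ok
        )
        if self.passed != expected:
            raise ValueError(f"{self.contig_id}: inconsistent verdict flags")

    @property
    def in_viral_pool(self) -> bool:
        """Passed the sequence screen and not flagged as DNA-encoded."""
        return self.passed and not self.genomic_origin


def remove_homologous(contigs: list[SequenceRecord], hits: Iterable[HitRecord],
                      evalue_max: float = 1e-5) -> list[SequenceRecord]:
    """Keep exactly the contigs with no hit at E-value <= cutoff."""
    contig_ids = {c.id for c in contigs}
    hit_ids = set()
    unknown = set()
    for h in hits:
        if h.query_id not in contig_ids:
            unknown.add(h.query_id)
            continue
        if h.evalue <= evalue_max:
            hit_ids.add(h.query_id)
    if unknown:
        warnings.warn(
            f"{len(unknown)} hit query id(s) not among the contigs (ignored)",
            stacklevel=2,
        )
    return [c for c in contigs if c.id not in hit_ids]


def evaluate_orfan(contig: SequenceRecord, counts: StrandCounts, orfs,
                   params: OrfanParams = OrfanParams(),
                   has_homology: bool = False,
                   dna_positive: Optional[bool] = None) -> OrfanVerdict:
    """Apply the size / coding / replication-signature criteria to one contig.

    ``orfs`` must be the ORFs predicted on this contig (both strands). The
    contig is oriented so its longest ORF defines the sense strand; the
    antisense/sense ratio is computed on the re-oriented counts.
    """
    cc = counts.get(contig.id)
    len_ok = len(contig) > params.min_contig_len
    longest = orfs[0] if orfs else None
    longest_len = longest.protein_len if longest else 0
    orf_ok = longest_len >= params.min_protein_len

    n_sense, n_antisense = cc.n_sense, cc.n_antisense
    if longest is not None and longest.strand == "-":
        n_sense, n_antisense = n_antisense, n_sense

    both_strands_ok = n_sense > 0 and n_antisense > 0
    ratio = n_antisense / n_sense if n_sense > 0 else None
    ratio_ok = ratio is not None and ratio >= params.min_strand_ratio

    passed = (not has_homology) and len_ok and orf_ok and both_strands_ok and ratio_ok
    return OrfanVerdict(
        contig_id=contig.id,
        has_homology=has_homology,
        len_ok=len_ok,
        orf_ok=orf_ok,
        both_strands_ok=both_strands_ok,
        ratio_ok=ratio_ok,
        antisense_ratio=ratio,
        longest_orf_len=longest_len,
        passed=passed,
        genomic_origin=dna_positive,
    )


def screen(contigs: list[SequenceRecord], hits: Iterable[HitRecord],
           counts: StrandCounts, params: OrfanParams = OrfanParams(),
           genetic_code: str = "standard",
           dna_positive: Optional[dict] = None) -> list[OrfanVerdict]:
    """Full ORFan screen: homology exclusion, then per-contig evaluation.

    Returns one verdict per surviving (non-homologous) contig, sorted by
    contig id. ``dna_positive`` optionally maps contig id -> bool from a
    DNA-integration assay.
    """
    survivors = remove_homologous(contigs, hits, params.evalue_max)
    dna_positive = dna_positive or {}
    verdicts = []
    for contig in sorted(survivors, key=lambda c: c.id):
        orfs = find_orfs(contig, genetic_code=genetic_code, min_aa=1)
        verdicts.append(
            evaluate_orfan(
                contig, counts, orfs, params,
                has_homology=False,
                dna_positive=dna_positive.get(contig.id),
            )
        )
    n_passed = sum(v.passed for v in verdicts)
    logger.info(
        "ORFan screen: %d contigs in, %d candidates after homology exclusion, %d passed",
        len(contigs), len(verdicts), n_passed,
    )
    return verdicts


def verdicts_to_dataframe(verdicts: list[OrfanVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": v.contig_id,
                "len_ok": v.len_ok,
                "orf_ok": v.orf_ok,
                "both_strands_ok": v.both_strands_ok,
                "ratio_ok": v.ratio_ok,
                "antisense_ratio": (
                    round(v.antisense_ratio, 4) if v.antisense_ratio is not None else ""
                ),
                "longest_orf_aa": v.longest_orf_len,
                "passed": v.passed,
                "genomic_origin": "" if v.genomic_origin is None else v.genomic_origin,
            }
            for v in verdicts
        ]
    )
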