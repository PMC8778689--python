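"""Readers and writers for the formats the screening pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython's :mod:`Bio.SeqIO`; this
module wraps it in light record types that carry the conventions the rest of
the package relies on:

* nucleotide residues are stored uppercase with ``U`` normalised to ``T``
  (deposited RNA virus genomes are DNA-alphabet records; RNA-alphabet strings
  are rendered only for display, e.g. the slippage tetranucleotide);
* all coordinates downstream are 1-based and inclusive on the forward strand
  of the stored sequence;
* synthetic reads may carry a ``strand=sense|antisense`` header tag holding
  the ground-truth orientation used by parameter-recovery tests.

All readers accept plain or gzip-compressed files (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "ReadRecord",
    "HitRecord",
    "InfectionTableRow",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_hit_table",
    "read_infection_table",
    "reverse_complement",
    "to_rna",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_NT_RE = re.compile(r"^[ACGTRYSWKMBDHVN]+$")
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYBXZJUO*]+$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Render a stored DNA-alphabet string in the RNA alphabet (T -> U)."""
    return seq.replace("T", "U").replace("t", "u")


@dataclass
class SequenceRecord:
    """An identified nucleotide or amino-acid sequence with provenance."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nucleotide"  # or "protein"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a whitespace-free token: {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id}: empty residue string")
        res = self.residues.upper()
        if self.alphabet == "nucleotide":
            res = res.replace("U", "T")
            if not _NT_RE.match(res):
                raise ValueError(f"record {self.id}: non-nucleotide residues")
        elif self.alphabet == "protein":
            if not _AA_RE.match(res):
                raise ValueError(f"record {self.id}: non-protein residues")
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.residues = res

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "nucleotide":
            raise TypeError("reverse complement is defined for nucleotide records")
        return SequenceRecord(
            id=self.id,
            residues=reverse_complement(self.residues),
            description=self.description,
            alphabet="nucleotide",
        )


@dataclass
class ReadRecord:
    """A sequencing read, optionally annotated with its true strand of origin."""

    id: str
    residues: str
    qualities: Optional[str] = None
    truth_strand: Optional[str] = None  # "sense" | "antisense" | None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise FormatError(
                f"read {self.id}: quality string length {len(self.qualities)} "
                f"!= sequence length {len(self.residues)}"
            )
        if self.truth_strand not in (None, "sense", "antisense"):
            raise ValueError(f"read {self.id}: bad truth_strand {self.truth_strand!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HitRecord:
    """One row of a 12-column homology hit table (outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: q_start > q_end")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative evalue")


@dataclass
class InfectionTableRow:
    """Detections for one yeast strain: virus column -> threshold cycle."""

    strain: str
    detections: dict = field(default_factory=dict)  # virus name -> (isolate, ct)

    def __post_init__(self) -> None:
        for virus, (_isolate, ct) in self.detections.items():
            if ct is not None and ct <= 0:
                raise ValueError(f"strain {self.strain}, {virus}: non-positive Ct")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Residues are concatenated across wrapped lines and uppercased; ``U`` is
    normalised to ``T`` for nucleotide records. An empty file yields an empty
    list with a warning; sequence data before the first ``>`` header is a
    :class:`FormatError`.
    """
    with _open_text(path) as handle:
        text_start = handle.read(1)
        if text_start == "":
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
        if text_start not in (">", ";", "\n"):
            raise FormatError(f"{path}: sequence data before first FASTA header")
        handle.seek(0)
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq),
                    description=desc,
                    alphabet=alphabet,
                )
            )
    if not records:
        warnings.warn(f"{path}: FASTA file contains no records", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, wrap: int = 60) -> None:
    with open(path, "wt") as out:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            out.write(header + "\n")
            res = rec.residues
            for i in range(0, len(res), wrap):
                out.write(res[i : i + wrap] + "\n")


_STRAND_TAG_RE = re.compile(r"strand=(sense|antisense)")


def read_fastq(path) -> list[ReadRecord]:
    """Parse 4-line FASTQ records; length-mismatched qualities raise FormatError.

    A ``strand=sense`` / ``strand=antisense`` token anywhere in the header
    populates :attr:`ReadRecord.truth_strand` (fixture-generated reads only).
    """
    reads = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                m = _STRAND_TAG_RE.search(rec.description)
                quals = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                reads.append(
                    ReadRecord(
                        id=rec.id,
                        residues=str(rec.seq),
                        qualities=quals,
                        truth_strand=m.group(1) if m else None,
                    )
                )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "wt") as out:
        for read in reads:
            tag = f" strand={read.truth_strand}" if read.truth_strand else ""
            quals = read.qualities or "I" * len(read.residues)
            out.write(f"@{read.id}{tag}\n{read.residues}\n+\n{quals}\n")


_HIT_COLUMNS = 12


def read_hit_table(path, evalue_max: float = float("inf")) -> list[HitRecord]:
    """Read a 12-column tab-separated homology hit table.

    Rows with ``evalue > evalue_max`` are excluded; raising the cutoff never
    removes previously kept rows. Extra columns beyond 12 are ignored with a
    warning; a non-numeric E-value raises a :class:`FormatError` naming the
    offending line. An empty file means no contig has homology.
    """
    hits: list[HitRecord] = []
    warned_extra = False
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(fields)}"
                )
            if len(fields) > _HIT_COLUMNS and not warned_extra:
                warnings.warn(
                    f"{path}:{lineno}: more than {_HIT_COLUMNS} columns; extras ignored",
                    stacklevel=2,
                )
                warned_extra = True
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric evalue {fields[10]!r}"
                ) from exc
            if evalue > evalue_max:
                continue
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=evalue,
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    with open(path, "wt") as out:
        for h in hits:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.pct_identity, h.aln_len,
                        h.mismatches, h.gap_opens, h.q_start, h.q_end,
                        h.s_start, h.s_end, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


def best_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Per-query best hit (lowest E-value, ties broken by higher bitscore)."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[h.query_id] = h
    return best


# Infection-table cell: "isolate-name(threshold-cycle)". Whitespace tolerated.
_CELL_RE = re.compile(r"^\s*(?P<isolate>[^()]*?)\s*\(\s*(?P<ct>[0-9]+(?:\.[0-9]+)?)\s*\)\s*$")


def read_infection_table(path) -> list[InfectionTableRow]:
    """Read a per-strain virus detection matrix.

    First column is the strain, remaining columns are virus names; cells are
    either empty (no detection) or ``isolate(ct)`` where ``ct`` is the
    real-time PCR threshold cycle on cDNA.
    """
    rows: list[InfectionTableRow] = []
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n")
        if not header.strip():
            raise FormatError(f"{path}: missing header line")
        virus_names = header.split("\t")[1:]
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            strain = cells[0].strip()
            detections = {}
            for virus, cell in zip(virus_names, cells[1:]):
                if not cell.strip():
                    continue
                m = _CELL_RE.match(cell)
                if not m:
                    raise FormatError(
                        f"{path}:{lineno}: unparseable detection cell {cell!r}"
                    )
                detections[virus] = (m.group("isolate"), float(m.group("ct")))
            rows.append(InfectionTableRow(strain=strain, detections=detections))
    return rows
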