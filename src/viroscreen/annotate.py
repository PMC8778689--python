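"""ORF prediction under selectable genetic codes and viral sequence features.

Covers the annotation steps that turn a candidate contig into a
characterised viral genome:

* complete-ORF prediction (ATG -> stop, both strands, all frames) under the
  standard code or the mold-mitochondrial code (translation table 4, where
  UGA reads through as Trp) — the code choice that separates cytoplasmic RNA
  viruses from mitoviruses;
* -1 ribosomal slippage detection as the coordinate overlap between two
  same-strand ORFs (totivirus CP/RdRp expression);
* RdRp motif scanning: exact search for the hallmark GDD tripeptide plus six
  degenerate consensus motifs (I-VI) shipped as editable data;
* the killer-toxin (K2-type) preprotoxin checklist: N-terminal hydrophobic
  region, three N-glycosylation sequons, and the two KR protease cleavage
  sites matured by KEX1/KEX2;
* premature (internal) stop-codon detection for defective satellite ORFs.

Coordinates are 1-based and inclusive. ORF coordinates refer to the forward
strand of the stored sequence; motif, toxin and stop positions are 1-based
within the analysed protein or ORF region.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from statistics import fmean

from Bio.Data import CodonTable
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .seqio import SequenceRecord, reverse_complement, to_rna

__all__ = [
    "OrfRecord",
    "OverlapRecord",
    "MotifHit",
    "ToxinReference",
    "ToxinReport",
    "StopRecord",
    "GENETIC_CODES",
    "find_orfs",
    "maximal_orfs",
    "detect_slippage_overlap",
    "scan_rdrp_motifs",
    "motif_series_complete",
    "validate_k2_preprotoxin",
    "detect_premature_stop",
]

# NCBI translation table ids; "mold_mitochondrial" is the standard choice for
# fungal mitoviruses (table 4: UGA -> Trp).
GENETIC_CODES = {"standard": 1, "mold_mitochondrial": 4}

START_CODON = "ATG"


def _code_tables(genetic_code: str):
    if genetic_code not in GENETIC_CODES:
        raise ValueError(
            f"unknown genetic code {genetic_code!r}; expected one of {sorted(GENETIC_CODES)}"
        )
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODES[genetic_code]]
    return dict(table.forward_table), set(table.stop_codons)


@dataclass
class OrfRecord:
    """A complete predicted open reading frame (initiator through stop)."""

    contig_id: str
    start: int  # 1-based inclusive, forward strand of the stored sequence
    end: int    # includes the stop codon
    strand: str  # "+" | "-"
    frame: int   # 1..3 on the ORF's own strand
    genetic_code: str
    protein: str  # translation, stop excluded
    complete: bool = True

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        if self.complete:
            if length % 3:
                raise ValueError(f"ORF {self.contig_id}:{self.start}-{self.end} not codon-sized")
            if len(self.protein) != length // 3 - 1:
                raise ValueError(
                    f"ORF {self.contig_id}:{self.start}-{self.end}: protein length mismatch"
                )

    @property
    def protein_len(self) -> int:
        return len(self.protein)


def find_orfs(seq: SequenceRecord, genetic_code: str = "standard",
              min_aa: int = 1, strands: str = "both") -> list[OrfRecord]:
    """All complete ORFs (ATG -> in-frame stop) of at least ``min_aa`` residues.

    Both strands and all three frames are scanned; nested ATGs yield nested
    ORFs. Results are sorted by protein length descending (ties: by start,
    then '+' before '-'). Stop codons are defined by the chosen genetic code.
    """
    if seq.alphabet != "nucleotide":
        raise TypeError("find_orfs requires a nucleotide record")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    fwd_table, stop_codons = _code_tables(genetic_code)
    L = len(seq.residues)
    orfs: list[OrfRecord] = []
    strand_list = {"both": ("+", "-"), "+": ("+",), "-": ("-",)}[strands]
    for strand in strand_list:
        s = seq.residues if strand == "+" else reverse_complement(seq.residues)
        for frame0 in range(3):
            open_starts: list[int] = []
            for p in range(frame0, L - 2, 3):
                codon = s[p : p + 3]
                if codon in stop_codons:
                    for st in open_starts:
                        n_aa = (p - st) // 3
                        if n_aa < min_aa:
                            continue
                        protein = "".join(
                            fwd_table.get(s[q : q + 3], "X") for q in range(st, p, 3)
                        )
                        # map strand-local [st+1, p+3] to forward coordinates
                        if strand == "+":
                            start, end = st + 1, p + 3
                        else:
                            start, end = L - (p + 3) + 1, L - (st + 1) + 1
                        orfs.append(
                            OrfRecord(
                                contig_id=seq.id,
                                start=start,
                                end=end,
                                strand=strand,
                                frame=frame0 + 1,
                                genetic_code=genetic_code,
                                protein=protein,
                            )
                        )
                    open_starts = []
                elif codon == START_CODON:
                    open_starts.append(p)
    orfs.sort(key=lambda o: (-o.protein_len, o.start, o.strand, o.frame))
    return orfs


def maximal_orfs(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Longest ORF per (strand, stop codon) — drops nested same-stop ORFs.

    Useful when reporting a genome's "major" ORFs: every in-frame ATG nested
    inside a longer ORF otherwise yields its own record.
    """
    best: dict[tuple, OrfRecord] = {}
    for o in orfs:
        key = (o.strand, o.end if o.strand == "+" else o.start)
        if key not in best or o.protein_len > best[key].protein_len:
            best[key] = o
    return sorted(best.values(), key=lambda o: (-o.protein_len, o.start))


@dataclass
class OverlapRecord:
    """Coordinate overlap between two same-strand ORFs (slippage candidate)."""

    upstream_orf: OrfRecord
    downstream_orf: OrfRecord
    overlap_start: int
    overlap_end: int
    overlap_seq: str  # RNA alphabet, for display
    frameshift: int   # downstream frame - upstream frame, mod 3, as -1/0/+1

    def __post_init__(self) -> None:
        if self.overlap_start > self.overlap_end:
            raise ValueError("overlap_start > overlap_end")
        if len(self.overlap_seq) != self.overlap_end - self.overlap_start + 1:
            raise ValueError("overlap_seq length mismatch")


_FRAMESHIFT = {0: 0, 1: 1, 2: -1}


def detect_slippage_overlap(orf_a: OrfRecord, orf_b: OrfRecord,
                            seq: SequenceRecord) -> OverlapRecord | None:
    """Overlap between two ORFs on the same strand of ``seq``, or None.

    The returned record carries the overlap sequence in the RNA alphabet (the
    convention for reporting slippage sites such as AUGA) and the relative
    frameshift of the downstream ORF (-1 for the programmed slippage layout
    of bicistronic totiviruses).
    """
    if orf_a.contig_id != orf_b.contig_id or orf_a.contig_id != seq.id:
        raise ValueError("ORFs and sequence must belong to the same contig")
    if orf_a.strand != orf_b.strand:
        raise ValueError("slippage overlap is defined for same-strand ORFs")
    up, down = (orf_a, orf_b) if orf_a.start <= orf_b.start else (orf_b, orf_a)
    o_start = max(up.start, down.start)
    o_end = min(up.end, down.end)
    if o_start > o_end:
        return None
    return OverlapRecord(
        upstream_orf=up,
        downstream_orf=down,
        overlap_start=o_start,
        overlap_end=o_end,
        overlap_seq=to_rna(seq.residues[o_start - 1 : o_end]),
        frameshift=_FRAMESHIFT[(down.frame - up.frame) % 3],
    )


@dataclass
class MotifHit:
    motif_id: str  # "I".."VI" or "GDD"
    start: int     # 1-based aa position in the protein
    end: int
    matched_seq: str


MOTIF_ORDER = ["I", "II", "III", "IV", "V", "VI"]


def _load_motif_patterns() -> dict[str, str]:
    data = resources.files("viroscreen.data").joinpath("rdrp_motifs.json").read_text()
    return json.loads(data)["motifs"]


def scan_rdrp_motifs(protein: str, patterns: dict[str, str] | None = None) -> list[MotifHit]:
    """Locate the GDD tripeptide and the consensus motifs I-VI in an RdRp.

    GDD is an exact search and every occurrence is reported; each consensus
    motif contributes at most one hit (its first match). Missing motifs are
    simply absent from the result; use :func:`motif_series_complete` to check
    for a full, collinear I-VI series.
    """
    if isinstance(protein, SequenceRecord):
        if protein.alphabet != "protein":
            raise TypeError("motif scan requires a protein sequence")
        protein = protein.residues
    protein = protein.upper()
    if patterns is None:
        patterns = _load_motif_patterns()
    hits: list[MotifHit] = []
    for motif_id in MOTIF_ORDER:
        pat = patterns.get(motif_id)
        if pat is None:
            continue
        m = re.search(pat, protein)
        if m:
            hits.append(
                MotifHit(motif_id=motif_id, start=m.start() + 1, end=m.end(),
                         matched_seq=m.group(0))
            )
    for m in re.finditer("GDD", protein):
        hits.append(MotifHit(motif_id="GDD", start=m.start() + 1, end=m.end(),
                             matched_seq="GDD"))
    return hits


def motif_series_complete(hits: list[MotifHit]) -> bool:
    """True iff motifs I-VI are all present in increasing position order."""
    pos = {}
    for h in hits:
        if h.motif_id in MOTIF_ORDER and h.motif_id not in pos:
            pos[h.motif_id] = h.start
    if any(m not in pos for m in MOTIF_ORDER):
        return False
    starts = [pos[m] for m in MOTIF_ORDER]
    return all(x < y for x, y in zip(starts, starts[1:]))


@dataclass
class ToxinReference:
    """Feature coordinates of the K2-type preprotoxin checklist.

    Windows are 1-based aa positions on the preprotoxin: an N-terminal
    hydrophobic stretch, three potential N-glycosylation sites (4-aa windows;
    the sequon test N-X-[S/T], X != P, applies to the first three positions)
    and the two KR dibasic sites cleaved by the KEX1 and KEX2 proteases.
    """

    hydrophobic_region: tuple[int, int] = (27, 45)
    glyc_sites: tuple[tuple[int, int], ...] = ((177, 180), (214, 217), (261, 264))
    kex1_site: tuple[int, int] = (220, 221)
    kex2_site: tuple[int, int] = (267, 268)
    expected_site_residues: str = "KR"


@dataclass
class ToxinReport:
    """Per-feature pass/fail of the preprotoxin checklist."""

    features: dict = field(default_factory=dict)   # name -> "pass"|"fail"|"not_evaluable"
    details: dict = field(default_factory=dict)    # name -> human-readable note
    substitutions: list = field(default_factory=list)  # (pos, ref_aa, obs_aa)

    @property
    def all_evaluable_passed(self) -> bool:
        return all(v != "fail" for v in self.features.values())


def _as_protein_string(protein) -> str:
    if isinstance(protein, SequenceRecord):
        if protein.alphabet != "protein":
            raise TypeError("preprotoxin validation requires a protein sequence")
        return protein.residues
    if not isinstance(protein, str):
        raise TypeError("protein must be a string or protein SequenceRecord")
    return protein.upper()


def validate_k2_preprotoxin(protein, reference: SequenceRecord | str | None = None,
                            windows: ToxinReference | None = None) -> ToxinReport:
    """Check a killer-preprotoxin candidate against the K2 feature checklist.

    Hydrophobicity is mean Kyte-Doolittle hydropathy > 0 over the N-terminal
    window; each glycosylation window must carry an N-X-[S/T] sequon (X != P)
    at its first three positions; both KEX sites must read exactly "KR" (a
    failure names the observed dipeptide). Features whose windows extend past
    the protein are marked "not_evaluable". When a reference preprotoxin is
    supplied, position-wise substitutions are listed against it.
    """
    p = _as_protein_string(protein)
    w = windows or ToxinReference()
    report = ToxinReport()

    lo, hi = w.hydrophobic_region
    if len(p) >= hi:
        mean_kd = fmean(KYTE_DOOLITTLE.get(c, 0.0) for c in p[lo - 1 : hi])
        report.features["hydrophobic_27_45"] = "pass" if mean_kd > 0 else "fail"
        report.details["hydrophobic_27_45"] = f"mean Kyte-Doolittle {mean_kd:+.2f} over aa {lo}-{hi}"
    else:
        report.features["hydrophobic_27_45"] = "not_evaluable"
        report.details["hydrophobic_27_45"] = f"protein shorter than {hi} aa"

    for start, end in w.glyc_sites:
        name = f"glyc_{start}_{end}"
        if len(p) >= start + 2:
            sequon = p[start - 1 : start + 2]
            ok = sequon[0] == "N" and sequon[1] != "P" and sequon[2] in "ST"
            report.features[name] = "pass" if ok else "fail"
            report.details[name] = (
                f"sequon {sequon} at aa {start}-{start + 2}"
                + (f" (window 4th residue: {p[end - 1]})" if len(p) >= end else "")
            )
        else:
            report.features[name] = "not_evaluable"
            report.details[name] = f"positions >= {len(p) + 1} not evaluable"

    for name, (start, end) in (("kex1_220_221", w.kex1_site), ("kex2_267_268", w.kex2_site)):
        if len(p) >= end:
            dipeptide = p[start - 1 : end]
            if dipeptide == w.expected_site_residues:
                report.features[name] = "pass"
                report.details[name] = f"{dipeptide} at aa {start}-{end}"
            else:
                report.features[name] = "fail"
                report.details[name] = (
                    f"expected {w.expected_site_residues} at aa {start}-{end}, observed {dipeptide}"
                )
        else:
            report.features[name] = "not_evaluable"
            report.details[name] = f"positions >= {len(p) + 1} not evaluable"

    if reference is not None:
        ref = _as_protein_string(reference)
        for i, (r, o) in enumerate(zip(ref, p), start=1):
            if r != o:
                report.substitutions.append((i, r, o))
    return report


@dataclass
class StopRecord:
    """Internal stop codons within an analysed ORF region."""

    positions: list[int]  # 1-based first-nt position of each stop, within the region
    defective: bool

    def __post_init__(self) -> None:
        if self.defective != bool(self.positions):
            raise ValueError("defective flag inconsistent with positions")


def detect_premature_stop(seq: SequenceRecord, orf_region: tuple[int, int],
                          genetic_code: str = "standard") -> StopRecord:
    """Find in-frame stop codons strictly before the final codon of a region.

    ``orf_region`` is (start, end), 1-based inclusive on the forward strand;
    the start position defines the reading frame. Positions are reported
    1-based *within the region*. Trailing bases that do not fill a codon are
    ignored with a warning.
    """
    start, end = orf_region
    if start < 1 or end > len(seq.residues) or start > end:
        raise ValueError(f"ORF region {orf_region} outside sequence {seq.id}")
    _, stop_codons = _code_tables(genetic_code)
    region = seq.residues[start - 1 : end]
    if len(region) % 3:
        warnings.warn(
            f"{seq.id}: ORF region length {len(region)} not a multiple of 3; "
            f"trailing {len(region) % 3} base(s) ignored",
            stacklevel=2,
        )
    n_codons = len(region) // 3
    positions = [
        3 * c + 1
        for c in range(n_codons - 1)  # strictly before the final codon
        if region[3 * c : 3 * c + 3] in stop_codons
    ]
    return StopRecord(positions=positions, defective=bool(positions))
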