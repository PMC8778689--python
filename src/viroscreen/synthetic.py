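"""Synthetic virome fixtures with planted, verifiable ground truth.

Generates the statistical structure the screening pipeline assumes, at desk
scale, with a truth manifest for parameter-recovery tests:

* host mRNA-like contigs with near-zero antisense read fractions (ordinary
  transcription produces essentially single-stranded reads);
* viral elements with substantial antisense fractions (the double-stranded
  replication intermediate), in the genome architectures the screen
  encounters: a bicistronic totivirus-like element whose CP and RdRp ORFs
  overlap by 4 nt in the -1 frame at an AUGA slippage site; monocistronic
  narnavirus- and mitovirus-like RdRp elements (the latter encoded under the
  mold-mitochondrial code with internal UGA-Trp codons); a bipartite
  partitivirus-like pair (RdRp and CP segments); a satellite element
  encoding a killer-preprotoxin with the K2 feature checklist (optionally
  carrying a planted premature stop); and "ORFan" elements with no known
  relative;
* sequence-variant pairs at controlled identity (exact mutation counts).

Element defaults reproduce the coordinates of the study system this package
targets: the totivirus-like element is 5878 nt with 942 aa CP / 882 aa RdRp
ORFs overlapping at nt 3166-3169 (AUGA); the mitovirus-like RdRp is 714 aa
with motifs I-VI and the GDD core planted in order; the narnavirus-like
RdRp is 829 aa; the preprotoxin is 362 aa.

Coding regions are reverse-translated codon-by-codon, so the only in-frame
stops are planted ones. UTRs are sampled free of ATG and CAT trinucleotides
so no open reading frame can initiate in (or run into) them on either
strand; every element is verified against its own truth before emission
(and re-drawn on the rare chance collision, e.g. a spurious upstream motif
match).

Reads are single-end, uniform-start, error-free by default; each read
carries its true strand in the header. Hit tables mark host contigs and
elements with known relatives; ORFan elements are absent from them — a
virus with no database relative enters the ORFan screen by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import annotate
from .seqio import (
    HitRecord,
    ReadRecord,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_fastq,
    write_hit_table,
)

__all__ = [
    "ConfigError",
    "ElementSpec",
    "SyntheticConfig",
    "ContigTruth",
    "TruthManifest",
    "default_elements",
    "generate_virome",
    "mutate_to_identity",
    "simulate_reads",
    "emit_hit_table",
    "write_fixture",
]

NT = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

ELEMENT_KINDS = (
    "toti_bicistronic",
    "narna_mono",
    "mito_mono",
    "partiti_bipartite",
    "satellite_toxin",
    "orfan_like",
)

# planted instances for the shipped RdRp motif patterns, in scan order
MOTIF_INSTANCES = {
    "I": "KADLAWG",
    "II": "GLTAADP",
    "III": "DKAFSGL",
    "IV": "SLAGDDV",  # carries the GDD catalytic core
    "V": "KLAAWEG",
    "VI": "EWKAAGS",
}
# 1-based aa start positions of the planted motifs in the mito-like RdRp
MOTIF_POSITIONS = {"I": 150, "II": 210, "III": 270, "IV": 330, "V": 390, "VI": 450}

HYDROPHOBIC_AA = "AVILMFC"  # all with positive Kyte-Doolittle hydropathy


class ConfigError(ValueError):
    """Raised when a synthetic specification is internally infeasible."""


@dataclass
class ElementSpec:
    """One planted viral element; unspecified sizes use the kind's defaults."""

    kind: str
    name: str
    length: int = 0                  # 0 -> kind default
    antisense_frac: float = 0.2
    genetic_code: str = "standard"
    has_known_relative: bool = True
    orf_aa: int = 0                  # mono kinds / satellite / orfan; 0 -> default
    cp_aa: int = 942                 # toti_bicistronic only
    rdrp_aa: int = 882               # toti_bicistronic only
    utr5: int = -1                   # -1 -> default
    rna2_length: int = 1321          # partiti_bipartite only
    rna2_orf_aa: int = 320           # partiti_bipartite only
    premature_stop_at: Optional[int] = None  # 1-based nt within the ORF region
    plant_motifs: bool = False
    plant_toxin_sites: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ConfigError(f"unknown element kind {self.kind!r}")
        if not 0 <= self.antisense_frac <= 1:
            raise ConfigError("antisense_frac must be in [0, 1]")


_KIND_DEFAULTS = {
    # kind: (length, orf_aa, genetic_code)
    "narna_mono": (2495, 829, "standard"),
    "mito_mono": (2465, 714, "mold_mitochondrial"),
    "satellite_toxin": (1165, 362, "standard"),
    "orfan_like": (1875, 400, "standard"),
    "toti_bicistronic": (5878, 0, "standard"),
    "partiti_bipartite": (1689, 486, "standard"),
}


def default_elements(n_orfan: int = 3) -> list[ElementSpec]:
    """The study-like element set: five known-virus architectures + ORFans."""
    elements = [
        ElementSpec(kind="toti_bicistronic", name="toti1", utr5=340),
        ElementSpec(kind="satellite_toxin", name="sat1", plant_toxin_sites=True),
        ElementSpec(kind="narna_mono", name="narna1"),
        ElementSpec(kind="mito_mono", name="mito1",
                    genetic_code="mold_mitochondrial", plant_motifs=True),
        ElementSpec(kind="partiti_bipartite", name="partiti1"),
    ]
    orfan_sizes = [(1404, 300), (1875, 400), (2637, 500)]
    for i in range(n_orfan):
        length, aa = orfan_sizes[i % len(orfan_sizes)]
        elements.append(
            ElementSpec(kind="orfan_like", name=f"orfan{i + 1}", length=length,
                        orf_aa=aa, has_known_relative=False)
        )
    return elements


@dataclass
class SyntheticConfig:
    seed: int = 42
    n_host: int = 50
    host_len: tuple[int, int] = (800, 3000)
    elements: list[ElementSpec] = field(default_factory=default_elements)
    read_len: int = 100
    depth: float = 300.0             # mean reads per contig (Poisson)
    host_antisense_frac: float = 0.005
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for frac in (self.host_antisense_frac, self.error_rate):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must be in [0, 1]")


@dataclass
class ContigTruth:
    kind: str                       # "host" or an element kind
    element: str                    # element name ("" for hosts)
    antisense_frac: float
    has_known_relative: bool
    genetic_code: str = "standard"
    features: dict = field(default_factory=dict)


@dataclass
class TruthManifest:
    contigs: dict = field(default_factory=dict)  # contig_id -> ContigTruth

    def to_json(self, path) -> None:
        payload = {cid: asdict(t) for cid, t in sorted(self.contigs.items())}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(contigs={cid: ContigTruth(**t) for cid, t in payload.items()})


# ---------------------------------------------------------------------------
# sequence construction helpers

def _codon_options(genetic_code: str) -> dict[str, list[str]]:
    fwd, _stops = annotate._code_tables(genetic_code)
    options: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        options.setdefault(aa, []).append(codon)
    for aa in options:
        options[aa].sort()
    return options


def _sample_utr(rng: np.random.Generator, n: int) -> str:
    """Random UTR free of ATG and CAT, so no ORF can initiate in it."""
    out: list[str] = []
    while len(out) < n:
        c = NT[rng.integers(4)]
        tail = "".join(out[-2:]) + c
        if tail.endswith("ATG") or tail.endswith("CAT"):
            continue
        out.append(c)
    return "".join(out)


def _random_protein(rng: np.random.Generator, n_aa: int,
                    fixed: dict[int, str] | None = None) -> str:
    """Random protein starting with M; ``fixed`` maps 1-based position -> aa."""
    res = [AA20[i] for i in rng.integers(0, len(AA20), size=n_aa)]
    res[0] = "M"
    for pos, aa in (fixed or {}).items():
        res[pos - 1] = aa
    return "".join(res)


def _encode(protein: str, rng: np.random.Generator, genetic_code: str = "standard",
            forced_codons: dict[int, str] | None = None) -> str:
    """Reverse-translate with random synonymous codons (stop-free by construction)."""
    options = _codon_options(genetic_code)
    forced = forced_codons or {}
    codons = []
    for i, aa in enumerate(protein, start=1):
        if i in forced:
            codons.append(forced[i])
            continue
        opts = options[aa]
        codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


def _mono_layout(spec: ElementSpec) -> tuple[int, int, int]:
    """(length, orf_aa, utr5) for single-ORF kinds, with feasibility checks."""
    d_len, d_aa, _ = _KIND_DEFAULTS[spec.kind]
    length = spec.length or d_len
    orf_aa = spec.orf_aa or d_aa
    orf_nt = 3 * (orf_aa + 1)
    slack = length - orf_nt
    if slack < 4:
        raise ConfigError(
            f"{spec.name}: a {orf_aa} aa ORF ({orf_nt} nt) does not fit in {length} nt"
        )
    utr5 = spec.utr5 if spec.utr5 >= 0 else slack // 2
    if utr5 + orf_nt > length:
        raise ConfigError(f"{spec.name}: utr5 {utr5} leaves no room for the ORF")
    return length, orf_aa, utr5


def _build_mono(spec: ElementSpec, rng: np.random.Generator,
                contig_id: str) -> tuple[SequenceRecord, dict]:
    """Single-ORF element (narna/mito/orfan/satellite architectures)."""
    length, orf_aa, utr5 = _mono_layout(spec)
    code = spec.genetic_code
    fixed: dict[int, str] = {}
    forced_codons: dict[int, str] = {}
    features: dict = {}

    if spec.plant_motifs:
        if orf_aa < MOTIF_POSITIONS["VI"] + 10:
            raise ConfigError(f"{spec.name}: ORF too short for the motif series")
        for motif, start in MOTIF_POSITIONS.items():
            inst = MOTIF_INSTANCES[motif]
            for off, aa in enumerate(inst):
                fixed[start + off] = aa
        features["motifs"] = {m: s for m, s in MOTIF_POSITIONS.items()}
        features["gdd_aa_start"] = MOTIF_POSITIONS["IV"] + 3

    if spec.kind == "mito_mono":
        # internal UGA-Trp codons: split the ORF under the standard code
        for pos in (100, orf_aa - 100):
            fixed[pos] = "W"
            forced_codons[pos] = "TGA"
        features["tga_trp_positions"] = [100, orf_aa - 100]

    if spec.plant_toxin_sites:
        if orf_aa < 268:
            raise ConfigError(
                f"{spec.name}: toxin checklist needs >= 268 aa, got {orf_aa}"
            )
        for pos in range(27, 46):
            fixed[pos] = HYDROPHOBIC_AA[rng.integers(len(HYDROPHOBIC_AA))]
        for start, sequon in ((177, "NAS"), (214, "NAT"), (261, "NAS")):
            for off, aa in enumerate(sequon):
                fixed[start + off] = aa
        for start in (220, 267):
            fixed[start] = "K"
            fixed[start + 1] = "R"
        features["toxin_sites"] = True

    protein = _random_protein(rng, orf_aa, fixed)
    coding = _encode(protein, rng, code, forced_codons) + "TAA"
    if spec.premature_stop_at is not None:
        pos = spec.premature_stop_at
        if pos % 3 != 1 or pos >= len(coding) - 2:
            raise ConfigError(
                f"{spec.name}: premature stop at {pos} is not an internal codon start"
            )
        coding = coding[: pos - 1] + "TAA" + coding[pos + 2 :]
        features["premature_stop_at"] = pos

    utr3_len = length - utr5 - len(coding)
    seq = _sample_utr(rng, utr5) + coding + _sample_utr(rng, utr3_len)
    features.update(
        {
            "orf_start": utr5 + 1,
            "orf_end": utr5 + len(coding),
            "orf_strand": "+",
            "orf_aa": orf_aa,
            "protein": protein,
        }
    )
    return SequenceRecord(id=contig_id, residues=seq), features


def _build_toti(spec: ElementSpec, rng: np.random.Generator,
                contig_id: str) -> tuple[SequenceRecord, dict]:
    """Bicistronic element: CP ORF, then RdRp ORF overlapping 4 nt in -1 frame.

    The CP stop (UGA) and the RdRp initiator (AUG) share the AUGA overlap
    tetranucleotide. The last two CP codons are pinned so that the RdRp
    reading frame carries a stop immediately upstream of its AUG, which
    keeps the maximal RdRp ORF at exactly the planted length.
    """
    length = spec.length or _KIND_DEFAULTS["toti_bicistronic"][0]
    cp_aa, rdrp_aa = spec.cp_aa, spec.rdrp_aa
    cp_nt = 3 * (cp_aa + 1)      # incl. stop
    rdrp_nt = 3 * (rdrp_aa + 1)  # incl. stop
    utr5 = spec.utr5 if spec.utr5 >= 0 else 340
    total_coding = cp_nt + rdrp_nt - 4
    utr3 = length - utr5 - total_coding
    if utr3 < 0:
        raise ConfigError(
            f"{spec.name}: CP {cp_aa} aa + RdRp {rdrp_aa} aa do not fit in {length} nt"
        )
    # CP: aa[n-1] ends with T, aa[n] = AAA, so the -1 frame reads ...TAA ATG A
    cp = _random_protein(rng, cp_aa, {cp_aa - 1: "D", cp_aa: "K"})
    cp_coding = _encode(cp, rng, forced_codons={cp_aa - 1: "GAT", cp_aa: "AAA"})
    # RdRp: aa2 is forced to K (AAA) because its codon starts on the CP stop's A
    rdrp = _random_protein(rng, rdrp_aa, {2: "K"})
    rdrp_tail = _encode(rdrp[2:], rng) + "TAA"

    orf1_start = utr5 + 1
    orf1_end = utr5 + cp_nt                 # CP stop = TGA at orf1_end-2..orf1_end
    orf2_start = orf1_end - 3               # AUG overlapping the stop
    seq = (
        _sample_utr(rng, utr5)
        + cp_coding
        + "TGA"        # CP stop; with the preceding A this is the AUGA overlap
        + "AA"         # completes the RdRp's second codon (AAA = K)
        + rdrp_tail
        + _sample_utr(rng, utr3)
    )
    assert len(seq) == length
    features = {
        "orf1_start": orf1_start,
        "orf1_end": orf1_end,
        "orf1_aa": cp_aa,
        "orf2_start": orf2_start,
        "orf2_end": orf2_start + rdrp_nt - 1,
        "orf2_aa": rdrp_aa,
        "overlap_start": orf2_start,
        "overlap_end": orf1_end,
        "overlap_seq_rna": "AUGA",
        "frameshift": -1,
        "orf_strand": "+",
    }
    return SequenceRecord(id=contig_id, residues=seq), features


def _verify_element(contig: SequenceRecord, spec: ElementSpec, features: dict) -> bool:
    """Check that the emitted contig satisfies its planted truth."""
    code = spec.genetic_code
    if spec.kind == "toti_bicistronic":
        orfs = annotate.find_orfs(contig, "standard", min_aa=50)
        maximal = _maximal(orfs)
        if len(maximal) < 2:
            return False
        top2 = sorted(maximal[:2], key=lambda o: -o.protein_len)
        if (top2[0].protein_len, top2[1].protein_len) != (spec.cp_aa, spec.rdrp_aa):
            return False
        ov = annotate.detect_slippage_overlap(top2[0], top2[1], contig)
        return (
            ov is not None
            and (ov.overlap_start, ov.overlap_end) == (features["overlap_start"], features["overlap_end"])
            and ov.overlap_seq == "AUGA"
            and ov.frameshift == -1
        )
    orfs = annotate.find_orfs(contig, code, min_aa=30)
    maximal = _maximal(orfs)
    if spec.premature_stop_at is not None:
        stop = annotate.detect_premature_stop(
            contig, (features["orf_start"], features["orf_end"]), code
        )
        return stop.defective and stop.positions[0] == spec.premature_stop_at
    if not maximal:
        return False
    top = maximal[0]
    if (top.protein_len, top.start, top.strand) != (
        features["orf_aa"], features["orf_start"], "+"
    ):
        return False
    if spec.plant_motifs:
        hits = {h.motif_id: h.start for h in annotate.scan_rdrp_motifs(top.protein)}
        for motif, start in features["motifs"].items():
            if hits.get(motif) != start:
                return False
    if spec.plant_toxin_sites:
        if not annotate.validate_k2_preprotoxin(top.protein).all_evaluable_passed:
            return False
    return True


_maximal = annotate.maximal_orfs


_MAX_RETRIES = 50


def _build_element(spec: ElementSpec, rng: np.random.Generator
                   ) -> list[tuple[SequenceRecord, ContigTruth]]:
    """Build (and internally verify) the contig(s) for one element."""
    out = []
    if spec.kind == "partiti_bipartite":
        rna1 = ElementSpec(
            kind="orfan_like", name=spec.name,
            length=spec.length or _KIND_DEFAULTS["partiti_bipartite"][0],
            orf_aa=spec.orf_aa or _KIND_DEFAULTS["partiti_bipartite"][1],
        )
        rna2 = ElementSpec(
            kind="orfan_like", name=spec.name,
            length=spec.rna2_length, orf_aa=spec.rna2_orf_aa,
        )
        for seg, sub in (("RNA1", rna1), ("RNA2", rna2)):
            cid = f"{spec.name}_{seg}"
            contig, feats = _retry_build(sub, rng, cid)
            feats["segment"] = seg
            out.append(
                (contig, ContigTruth(
                    kind=spec.kind, element=spec.name,
                    antisense_frac=spec.antisense_frac,
                    has_known_relative=spec.has_known_relative,
                    genetic_code=spec.genetic_code, features=feats,
                ))
            )
        return out
    contig, feats = _retry_build(spec, rng, spec.name)
    out.append(
        (contig, ContigTruth(
            kind=spec.kind, element=spec.name,
            antisense_frac=spec.antisense_frac,
            has_known_relative=spec.has_known_relative,
            genetic_code=spec.genetic_code, features=feats,
        ))
    )
    return out


def _retry_build(spec: ElementSpec, rng: np.random.Generator, contig_id: str):
    builder = _build_toti if spec.kind == "toti_bicistronic" else _build_mono
    for _ in range(_MAX_RETRIES):
        contig, feats = builder(spec, rng, contig_id)
        if _verify_element(contig, spec, feats):
            return contig, feats
    raise ConfigError(
        f"{spec.name}: could not realise the element spec in {_MAX_RETRIES} draws"
    )


def generate_virome(config: SyntheticConfig
                    ) -> tuple[list[SequenceRecord], TruthManifest]:
    """Host contigs plus planted viral elements, with their truth manifest."""
    rng = np.random.default_rng([config.seed, 0])
    contigs: list[SequenceRecord] = []
    truth = TruthManifest()
    lo, hi = config.host_len
    for i in range(1, config.n_host + 1):
        cid = f"host{i}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(NT[j] for j in rng.integers(0, 4, size=length))
        contigs.append(SequenceRecord(id=cid, residues=seq))
        truth.contigs[cid] = ContigTruth(
            kind="host", element="", antisense_frac=config.host_antisense_frac,
            has_known_relative=True,
        )
    for spec in config.elements:
        for contig, contig_truth in _build_element(spec, rng):
            if contig.id in truth.contigs:
                raise ConfigError(f"duplicate contig id {contig.id!r}")
            contigs.append(contig)
            truth.contigs[contig.id] = contig_truth
    return contigs, truth


def mutate_to_identity(seq: SequenceRecord, target_pct: float,
                       alphabet: str = "nucleotide", seed: int = 0,
                       new_id: Optional[str] = None) -> SequenceRecord:
    """Substitution-only mutant at a controlled ungapped identity.

    Exactly ``round((100 - target) * L / 100)`` positions, sampled without
    replacement, are substituted to a different residue. Targets below the
    alphabet noise floor (25% nucleotide, 5% protein) are rejected.
    """
    if not 0 < target_pct <= 100:
        raise ConfigError("target identity must be in (0, 100]")
    floor = 25.0 if alphabet == "nucleotide" else 5.0
    if target_pct < floor:
        raise ConfigError(
            f"target {target_pct}% below the {alphabet} noise floor ({floor}%)"
        )
    letters = NT if alphabet == "nucleotide" else AA20
    rng = np.random.default_rng(seed)
    residues = list(seq.residues)
    n_mut = round((100.0 - target_pct) * len(residues) / 100.0)
    positions = rng.choice(len(residues), size=n_mut, replace=False)
    for pos in positions:
        current = residues[pos]
        choices = [c for c in letters if c != current]
        residues[pos] = choices[rng.integers(len(choices))]
    return SequenceRecord(
        id=new_id or f"{seq.id}_id{target_pct:g}",
        residues="".join(residues),
        alphabet=seq.alphabet,
    )


def simulate_reads(contigs: list[SequenceRecord], truth: TruthManifest,
                   config: SyntheticConfig,
                   rng: Optional[np.random.Generator] = None) -> list[ReadRecord]:
    """Single-end reads: Poisson(depth) per contig, uniform start positions.

    Each read is drawn antisense with its contig's antisense fraction (the
    reverse complement of the sampled window) and carries the truth strand
    in its header tag. Substitution errors are applied at ``error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    rl = config.read_len
    shortest = min(len(c) for c in contigs) if contigs else 0
    if contigs and rl > shortest:
        raise ConfigError(f"read_len {rl} exceeds shortest contig ({shortest} nt)")
    reads: list[ReadRecord] = []
    for contig in contigs:
        af = truth.contigs[contig.id].antisense_frac
        n = int(rng.poisson(config.depth))
        for i in range(n):
            start = int(rng.integers(0, len(contig) - rl + 1))
            frag = contig.residues[start : start + rl]
            antisense = bool(rng.random() < af)
            if antisense:
                frag = reverse_complement(frag)
            if config.error_rate > 0:
                bases = list(frag)
                for j in np.nonzero(rng.random(rl) < config.error_rate)[0]:
                    options = [c for c in NT if c != bases[j]]
                    bases[j] = options[rng.integers(3)]
                frag = "".join(bases)
            reads.append(
                ReadRecord(
                    id=f"{contig.id}_r{i:05d}",
                    residues=frag,
                    truth_strand="antisense" if antisense else "sense",
                )
            )
    return reads


def emit_hit_table(truth: TruthManifest) -> list[HitRecord]:
    """Synthetic homology outcome: every contig with a known relative gets one hit.

    ORFan-like elements get none — a virus absent from reference databases
    enters the ORFan screen whether or not it is viral, which is exactly the
    screen's blind spot (and its purpose).
    """
    hits = []
    for cid, t in sorted(truth.contigs.items()):
        if t.kind == "orfan_like" or not t.has_known_relative:
            continue
        subject = "refdb|host_mrna" if t.kind == "host" else f"refdb|{t.kind}"
        hits.append(
            HitRecord(
                query_id=cid, subject_id=subject, pct_identity=92.3,
                aln_len=300, mismatches=20, gap_opens=2,
                q_start=1, q_end=300, s_start=1, s_end=300,
                evalue=1e-50, bitscore=350.0,
            )
        )
    return hits


def write_fixture(config: SyntheticConfig, outdir) -> dict:
    """Write contigs.fasta, reads.fastq, hits.tsv and truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, truth = generate_virome(config)
    reads = simulate_reads(contigs, truth, config)
    hits = emit_hit_table(truth)
    write_fasta(contigs, outdir / "contigs.fasta")
    write_fastq(reads, outdir / "reads.fastq")
    write_hit_table(hits, outdir / "hits.tsv")
    truth.to_json(outdir / "truth.json")
    return {
        "contigs": outdir / "contigs.fasta",
        "reads": outdir / "reads.fastq",
        "hits": outdir / "hits.tsv",
        "truth": outdir / "truth.json",
    }
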