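"""Checks against the study's deposited GenBank records, when available.

The identity ranges, ORF sizes and feature coordinates this package is built
around were published for specific deposited sequences. None of those
records ship with the package (they are GenBank data, not ours); this module
runs the corresponding computations on a local drop-in directory of FASTA
files named ``<accession>.fasta`` (one record each, plain or gzipped), e.g.::

    data/accessions/OK412910.fasta

Download the accessions listed in :data:`ACCESSION_GROUPS` from GenBank into
that directory and every check below becomes runnable offline. Each check
recomputes a published quantity from the records: maximal ORF sizes, the
slippage overlap, a premature stop position, pairwise identities and
identity-range minima.
"""

from __future__ import annotations

from pathlib import Path

from .annotate import detect_premature_stop, detect_slippage_overlap, find_orfs, scan_rdrp_motifs
from .identity import identity_matrix, pairwise_identity, range_summary
from .seqio import SequenceRecord, read_fasta

__all__ = ["ACCESSION_GROUPS", "load_accession", "run_accession_checks"]

ACCESSION_GROUPS = {
    # 647 bp CP-gene fragments of the L-A helper totiviruses (12 isolates)
    "la_cp_set": [f"OK3770{n:02d}" for n in range(6, 18)],
    # 801 bp RdRp/CP fragments of the L-BC totiviruses (8 isolates)
    "lbc_set": [f"OK3770{n:02d}" for n in range(18, 26)],
    # single records used by the pairwise checks
    "sbtv1": ["OK412911"],
    "sbmv1": ["OK412910"],
    "mlus_d254": ["OK412909"],
    "narna_nda21": ["OK412912"],
    "sccv1_rna1": ["OK412915", "OK412916"],
    # references
    "scnv_20s_w": ["AF039063"],
    "lbc_la_ref": ["U01060"],
}


def load_accession(directory, accession: str) -> SequenceRecord:
    directory = Path(directory)
    for suffix in (".fasta", ".fa", ".fasta.gz", ".fa.gz"):
        path = directory / f"{accession}{suffix}"
        if path.exists():
            rec = read_fasta(path)[0]
            rec.id = accession
            return rec
    raise FileNotFoundError(f"{accession}: no FASTA found under {directory}")


def _maximal_orf_lengths(rec: SequenceRecord, code: str = "standard", top: int = 2):
    from .synthetic import _maximal

    orfs = _maximal(find_orfs(rec, code, min_aa=50))
    return [o.protein_len for o in orfs[:top]], orfs


def run_accession_checks(directory) -> dict:
    """Recompute the published quantities from locally deposited records.

    Returns a dict of computed values keyed by check name; raises
    FileNotFoundError (listing what is missing) when the directory does not
    hold the needed records.
    """
    directory = Path(directory)
    missing = [
        acc
        for accs in ACCESSION_GROUPS.values()
        for acc in accs
        if not any(
            (directory / f"{acc}{sfx}").exists()
            for sfx in (".fasta", ".fa", ".fasta.gz", ".fa.gz")
        )
    ]
    if missing:
        raise FileNotFoundError(
            f"deposited records missing under {directory}: {', '.join(missing)}"
        )

    out: dict = {}

    # bicistronic totivirus: ORF sizes and the slippage overlap
    sbtv1 = load_accession(directory, "OK412911")
    lengths, orfs = _maximal_orf_lengths(sbtv1)
    out["sbtv1_orf_aa"] = sorted(lengths, reverse=True)
    ov = detect_slippage_overlap(orfs[0], orfs[1], sbtv1)
    out["sbtv1_overlap"] = None if ov is None else {
        "start": ov.overlap_start, "end": ov.overlap_end,
        "seq": ov.overlap_seq, "frameshift": ov.frameshift,
    }

    # mitovirus RdRp under the mold-mitochondrial code; GDD presence
    sbmv1 = load_accession(directory, "OK412910")
    lengths, orfs = _maximal_orf_lengths(sbmv1, "mold_mitochondrial", top=1)
    out["sbmv1_rdrp_aa"] = lengths[0]
    out["sbmv1_gdd_present"] = any(
        h.motif_id == "GDD" for h in scan_rdrp_motifs(orfs[0].protein)
    )

    # defective satellite ORF: internal stop position in the K-lus frame
    mlus = load_accession(directory, "OK412909")
    orfs = find_orfs(mlus, min_aa=10)
    region_start = orfs[0].start if orfs else 1
    stop = detect_premature_stop(mlus, (region_start, len(mlus.residues)))
    out["mlus_internal_stops"] = stop.positions

    # pairwise identities
    rna1 = [load_accession(directory, a) for a in ACCESSION_GROUPS["sccv1_rna1"]]
    out["sccv1_rdrp_nt_pct"] = pairwise_identity(
        rna1[0].residues, rna1[1].residues
    ).pct_identity
    narna = load_accession(directory, "OK412912")
    ref20s = load_accession(directory, "AF039063")
    out["narna_vs_20s_nt_pct"] = pairwise_identity(
        narna.residues, ref20s.residues
    ).pct_identity
    lbc_la = load_accession(directory, "OK377018")
    u01060 = load_accession(directory, "U01060")
    out["lbc_la_vs_ref_nt_pct"] = pairwise_identity(
        lbc_la.residues, u01060.residues
    ).pct_identity

    # identity-range minima over the fragment sets
    for name, key in (("la_cp_set", "la_cp_min_pct"), ("lbc_set", "lbc_min_pct")):
        records = [load_accession(directory, a) for a in ACCESSION_GROUPS[name]]
        lo, _hi = range_summary(identity_matrix(records))
        out[key] = lo
    return out
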