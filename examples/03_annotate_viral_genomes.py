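"""Annotate the generated viral genomes: ORFs, slippage, motifs, toxin.

Shows the four annotation capabilities on architecture-faithful synthetic
genomes: the bicistronic totivirus-like element (CP/RdRp ORFs joined by a
-1 ribosomal slippage at an AUGA overlap), the mitovirus-like RdRp (mold
mitochondrial code, motifs I-VI and the GDD core), a killer-preprotoxin
satellite (K2 checklist), and a defective satellite with an internal stop.
"""

from viroscreen import (
    ElementSpec,
    SyntheticConfig,
    detect_premature_stop,
    detect_slippage_overlap,
    find_orfs,
    generate_virome,
    maximal_orfs,
    motif_series_complete,
    scan_rdrp_motifs,
    validate_k2_preprotoxin,
)

contigs, truth = generate_virome(SyntheticConfig(seed=42, n_host=0))
by_id = {c.id: c for c in contigs}

# --- bicistronic totivirus-like genome -----------------------------------
toti = by_id["toti1"]
cp, rdrp = maximal_orfs(find_orfs(toti, min_aa=50))[:2]
ov = detect_slippage_overlap(cp, rdrp, toti)
print(f"toti1 ({len(toti)} nt): CP {cp.protein_len} aa, RdRp {rdrp.protein_len} aa")
print(f"  slippage overlap {ov.overlap_seq} at nt {ov.overlap_start}-{ov.overlap_end}, "
      f"frameshift {ov.frameshift:+d}")

# --- mitovirus-like RdRp --------------------------------------------------
mito = by_id["mito1"]
top = maximal_orfs(find_orfs(mito, "mold_mitochondrial", min_aa=50))[0]
std = find_orfs(mito, "standard", min_aa=50)
hits = scan_rdrp_motifs(top.protein)
print(f"\nmito1 ({len(mito)} nt): RdRp {top.protein_len} aa under the mold "
      f"mitochondrial code (longest standard-code ORF: "
      f"{std[0].protein_len if std else 0} aa — internal UGA codons split it)")
print("  motifs: " + ", ".join(f"{h.motif_id}@{h.start}" for h in hits)
      + f"; series complete: {motif_series_complete(hits)}")

# --- killer-preprotoxin satellite ----------------------------------------
sat = by_id["sat1"]
tox = maximal_orfs(find_orfs(sat, min_aa=100))[0]
report = validate_k2_preprotoxin(tox.protein)
print(f"\nsat1 ({len(sat)} nt): preprotoxin {tox.protein_len} aa")
for feature, status in report.features.items():
    print(f"  {feature:18s} {status}")

# --- defective satellite with a premature stop ---------------------------
cfg = SyntheticConfig(seed=42, n_host=0, elements=[
    ElementSpec(kind="satellite_toxin", name="mlus", length=1165,
                orf_aa=362, premature_stop_at=232),
])
(mlus,), truth2 = generate_virome(cfg)
feats = truth2.contigs["mlus"].features
stop = detect_premature_stop(mlus, (feats["orf_start"], feats["orf_end"]))
print(f"\nmlus: internal stop at ORF nt {stop.positions}, defective={stop.defective}")
print(
    "Meaning: the annotator recovers every planted feature at its planted "
    "coordinate — the same calls used to characterise real viral contigs."
)
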