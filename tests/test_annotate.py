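import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from viroscreen import annotate
from viroscreen.seqio import SequenceRecord, reverse_complement

from oracles import brute_force_orfs

STOPS = ("standard", "mold_mitochondrial")


nt_seq = st.text(alphabet="ACGT", min_size=30, max_size=400)


class TestFindOrfs:
    @pytest.mark.parametrize(
        "residues, code, min_aa, proteins",
        [
            ("ATGAAATAA", "standard", 1, ["MK"]),
            ("ATGTGATAA", "standard", 2, []),
            ("ATGTGATAA", "mold_mitochondrial", 2, ["MW"]),
        ],
    )
    def test_genetic_code_semantics(self, residues, code, min_aa, proteins):
        seq = SequenceRecord(id="s", residues=residues)
        orfs = annotate.find_orfs(seq, code, min_aa=min_aa, strands="+")
        assert [o.protein for o in orfs] == proteins

    @given(nt_seq, st.sampled_from(list(STOPS)))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, residues, code):
        seq = SequenceRecord(id="s", residues=residues)
        got = {
            (o.start, o.end, o.strand, o.protein)
            for o in annotate.find_orfs(seq, code, min_aa=1)
        }
        assert got == brute_force_orfs(residues, code, 1)

    @given(nt_seq)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_strand_symmetry(self, residues):
        seq = SequenceRecord(id="s", residues=residues)
        rc = seq.reverse_complement()
        L = len(residues)
        mirrored = {
            (L - o.end + 1, L - o.start + 1, "-" if o.strand == "+" else "+", o.protein)
            for o in annotate.find_orfs(seq)
        }
        got = {(o.start, o.end, o.strand, o.protein) for o in annotate.find_orfs(rc)}
        assert got == mirrored

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="genetic code"):
            annotate.find_orfs(SequenceRecord(id="s", residues="ATGAAATAA"), "martian")

    def test_sorted_by_length_descending(self):
        # nested ATG gives a shorter nested ORF
        seq = SequenceRecord(id="s", residues="ATGATGAAATAA")
        lengths = [o.protein_len for o in annotate.find_orfs(seq, min_aa=1, strands="+")]
        assert lengths == sorted(lengths, reverse=True)


class TestSlippageOverlap:
    def orf(self, start, end, frame, cid="c"):
        n_aa = (end - start + 1) // 3 - 1
        return annotate.OrfRecord(
            contig_id=cid, start=start, end=end, strand="+", frame=frame,
            genetic_code="standard", protein="M" * n_aa,
        )

    def test_intersection_and_frameshift(self):
        seq = SequenceRecord(id="c", residues="ATGAAATAAATGAAATAAAT")
        ov = annotate.detect_slippage_overlap(self.orf(1, 9, 1), self.orf(7, 15, 1), seq)
        assert (ov.overlap_start, ov.overlap_end) == (7, 9)
        assert ov.overlap_seq == "UAA"  # RNA alphabet for display
        assert ov.frameshift == 0

    def test_disjoint_orfs_give_none(self):
        seq = SequenceRecord(id="c", residues="A" * 40)
        assert annotate.detect_slippage_overlap(self.orf(1, 9, 1), self.orf(13, 21, 1), seq) is None

    def test_minus_one_frameshift_reported(self):
        seq = SequenceRecord(id="c", residues="A" * 40)
        ov = annotate.detect_slippage_overlap(self.orf(1, 12, 1), self.orf(9, 20, 3), seq)
        assert ov.frameshift == -1

    def test_different_contigs_rejected(self):
        seq = SequenceRecord(id="c", residues="A" * 40)
        with pytest.raises(ValueError):
            annotate.detect_slippage_overlap(
                self.orf(1, 9, 1), self.orf(7, 15, 1, cid="other"), seq
            )


class TestMotifScan:
    def test_gdd_exact_search_all_occurrences(self):
        protein = "M" + "A" * 50 + "GDD" + "A" * 50 + "GDD" + "A" * 10
        hits = [h for h in annotate.scan_rdrp_motifs(protein) if h.motif_id == "GDD"]
        assert [h.start for h in hits] == [52, 105]
        assert all(h.matched_seq == protein[h.start - 1 : h.end] for h in hits)

    def test_shuffled_negative_control_incomplete_series(self):
        rng = np.random.default_rng(5)
        protein = "".join(rng.permutation(list("ACDEFGHIKLMNPQRSTVWY" * 10)))
        hits = annotate.scan_rdrp_motifs(protein)
        assert not annotate.motif_series_complete(hits)

    def test_position_stable_under_prepending(self, virome):
        _, truth = virome
        protein = truth.contigs["mito1"].features["protein"]
        base = annotate.scan_rdrp_motifs(protein)
        shifted = annotate.scan_rdrp_motifs("A" * 13 + protein)
        assert [(h.motif_id, h.start + 13) for h in base] == [
            (h.motif_id, h.start) for h in shifted
        ]

    def test_planted_series_found_in_order(self, virome):
        _, truth = virome
        protein = truth.contigs["mito1"].features["protein"]
        hits = annotate.scan_rdrp_motifs(protein)
        assert annotate.motif_series_complete(hits)
        positions = {h.motif_id: h.start for h in hits}
        assert positions["IV"] < positions["V"]
        assert any(h.motif_id == "GDD" for h in hits)


def make_toxin_protein(kex1="KR", kex2="KR"):
    p = list("M" + "Q" * 400)
    for i in range(26, 45):
        p[i] = "L"
    for start, sequon in ((177, "NAS"), (214, "NAT"), (261, "NAS")):
        p[start - 1 : start + 2] = sequon
    p[219:221] = kex1
    p[266:268] = kex2
    return "".join(p)


class TestToxinChecklist:
    def test_constructed_positive_passes_all_sites(self):
        report = annotate.validate_k2_preprotoxin(make_toxin_protein())
        assert set(report.features.values()) == {"pass"}

    def test_kex1_substitution_fails_and_is_named(self):
        mutant = make_toxin_protein(kex1="ER")
        report = annotate.validate_k2_preprotoxin(mutant, reference=make_toxin_protein())
        assert report.features["kex1_220_221"] == "fail"
        assert "ER" in report.details["kex1_220_221"]
        assert (220, "K", "E") in report.substitutions

    def test_short_protein_marked_not_evaluable(self):
        report = annotate.validate_k2_preprotoxin("M" + "L" * 99)
        assert report.features["glyc_177_180"] == "not_evaluable"
        assert report.features["kex2_267_268"] == "not_evaluable"

    def test_nucleotide_input_rejected(self):
        with pytest.raises(TypeError):
            annotate.validate_k2_preprotoxin(SequenceRecord(id="x", residues="ACGT"))


class TestPrematureStop:
    def test_internal_stop_found(self):
        seq = SequenceRecord(id="s", residues="ATGAAATAGAAATAA")
        rec = annotate.detect_premature_stop(seq, (1, 15))
        assert rec.positions == [7] and rec.defective

    def test_clean_orf_not_defective(self):
        seq = SequenceRecord(id="s", residues="ATGAAATAA")
        rec = annotate.detect_premature_stop(seq, (1, 9))
        assert rec.positions == [] and not rec.defective

    def test_trailing_bases_ignored_with_warning(self):
        seq = SequenceRecord(id="s", residues="ATGAAATAGAAATAAC")
        with pytest.warns(UserWarning, match="multiple of 3"):
            rec = annotate.detect_premature_stop(seq, (1, 16))
        assert rec.positions == [7]

    def test_code_dependent_stops(self):
        # TGA is a stop under the standard code but Trp under mold mitochondrial
        seq = SequenceRecord(id="s", residues="ATGTGAAAATAA")
        assert annotate.detect_premature_stop(seq, (1, 12), "standard").positions == [4]
        assert not annotate.detect_premature_stop(seq, (1, 12), "mold_mitochondrial").defective

    def test_generator_coding_regions_are_stop_free(self, virome):
        contigs, truth = virome
        by_id = {c.id: c for c in contigs}
        for cid, t in truth.contigs.items():
            feats = t.features
            if "orf_start" not in feats or "premature_stop_at" in feats:
                continue
            rec = annotate.detect_premature_stop(
                by_id[cid], (feats["orf_start"], feats["orf_end"]), t.genetic_code
            )
            assert not rec.defective, cid
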