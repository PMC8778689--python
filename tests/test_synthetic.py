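import numpy as np
import pytest

from viroscreen import annotate
from viroscreen.seqio import read_fasta, read_fastq
from viroscreen.synthetic import (
    ConfigError,
    ElementSpec,
    SyntheticConfig,
    emit_hit_table,
    generate_virome,
    mutate_to_identity,
    simulate_reads,
    write_fixture,
    _maximal,
)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SyntheticConfig(seed=11, n_host=5)
        p1 = write_fixture(cfg, tmp_path / "a")
        p2 = write_fixture(cfg, tmp_path / "b")
        for key in ("contigs", "reads", "hits", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_differs(self, tmp_path):
        c1 = write_fixture(SyntheticConfig(seed=11, n_host=5), tmp_path / "a")
        c2 = write_fixture(SyntheticConfig(seed=12, n_host=5), tmp_path / "b")
        assert c1["contigs"].read_bytes() != c2["contigs"].read_bytes()

    def test_fixture_files_parse_back(self, tmp_path):
        cfg = SyntheticConfig(seed=11, n_host=3)
        paths = write_fixture(cfg, tmp_path / "fx")
        contigs = read_fasta(paths["contigs"])
        reads = read_fastq(paths["reads"])
        assert len(contigs) == 3 + 9  # hosts + element contigs (bipartite pair + 3 ORFans)
        assert all(r.truth_strand in ("sense", "antisense") for r in reads)


class TestPlantedArchitectures:
    def test_toti_bicistronic_layout(self, virome):
        contigs, truth = virome
        toti = next(c for c in contigs if c.id == "toti1")
        feats = truth.contigs["toti1"].features
        maximal = _maximal(annotate.find_orfs(toti, min_aa=50))
        cp, rdrp = maximal[0], maximal[1]
        assert (cp.protein_len, rdrp.protein_len) == (942, 882)
        ov = annotate.detect_slippage_overlap(cp, rdrp, toti)
        assert (ov.overlap_start, ov.overlap_end) == (3166, 3169)
        assert ov.overlap_seq == "AUGA" and ov.frameshift == -1
        assert feats["overlap_start"] == 3166

    def test_mito_code_semantics(self, virome):
        contigs, _ = virome
        mito = next(c for c in contigs if c.id == "mito1")
        mold = annotate.find_orfs(mito, "mold_mitochondrial", min_aa=50)
        std = annotate.find_orfs(mito, "standard", min_aa=50)
        assert mold[0].protein_len == 714
        # internal UGA codons split the ORF under the standard code
        assert not std or std[0].protein_len < 714

    def test_narna_and_partiti_orf_lengths(self, virome):
        contigs, truth = virome
        for cid in ("narna1", "partiti1_RNA1", "partiti1_RNA2"):
            contig = next(c for c in contigs if c.id == cid)
            feats = truth.contigs[cid].features
            top = _maximal(annotate.find_orfs(contig, min_aa=30))[0]
            assert top.protein_len == feats["orf_aa"], cid
            assert top.start == feats["orf_start"]

    def test_satellite_toxin_checklist_passes(self, virome):
        contigs, truth = virome
        sat = next(c for c in contigs if c.id == "sat1")
        top = _maximal(annotate.find_orfs(sat, min_aa=100))[0]
        assert top.protein_len == 362
        report = annotate.validate_k2_preprotoxin(top.protein)
        assert set(report.features.values()) == {"pass"}

    def test_planted_premature_stop_recovered(self):
        cfg = SyntheticConfig(
            seed=5, n_host=0,
            elements=[ElementSpec(kind="satellite_toxin", name="mlus", length=1165,
                                  orf_aa=362, premature_stop_at=232)],
        )
        contigs, truth = generate_virome(cfg)
        feats = truth.contigs["mlus"].features
        rec = annotate.detect_premature_stop(
            contigs[0], (feats["orf_start"], feats["orf_end"])
        )
        assert rec.defective and rec.positions[0] == 232

    def test_infeasible_specs_rejected(self):
        with pytest.raises(ConfigError):
            generate_virome(SyntheticConfig(
                n_host=0,
                elements=[ElementSpec(kind="satellite_toxin", name="tiny", length=200,
                                      orf_aa=60, plant_toxin_sites=True)],
            ))
        with pytest.raises(ConfigError):
            generate_virome(SyntheticConfig(
                n_host=0,
                elements=[ElementSpec(kind="orfan_like", name="nofit", length=300,
                                      orf_aa=300)],
            ))


class TestMutateToIdentity:
    def seq(self, n=1000, seed=1):
        rng = np.random.default_rng(seed)
        from viroscreen.seqio import SequenceRecord

        return SequenceRecord(id="s", residues="".join("ACGT"[i] for i in rng.integers(0, 4, n)))

    def count_identity(self, a, b):
        same = sum(x == y for x, y in zip(a.residues, b.residues))
        return 100.0 * same / len(a.residues)

    def test_target_100_is_identical(self):
        s = self.seq()
        assert mutate_to_identity(s, 100, seed=3).residues == s.residues

    def test_exact_mutation_count(self):
        s = self.seq(1000)
        mut = mutate_to_identity(s, 90, seed=3)
        assert self.count_identity(s, mut) == 90.0  # exactly 100 substitutions

    @pytest.mark.parametrize("target", [77.6, 85.0, 94.75, 99.0])
    def test_ungapped_identity_close_to_target(self, target):
        s = self.seq(2000)
        mut = mutate_to_identity(s, target, seed=4)
        assert abs(self.count_identity(s, mut) - target) <= 0.5

    def test_below_noise_floor_rejected(self):
        with pytest.raises(ConfigError, match="noise floor"):
            mutate_to_identity(self.seq(), 20)


class TestReadsAndHits:
    def test_zero_antisense_fraction_all_sense(self):
        cfg = SyntheticConfig(
            seed=9, n_host=0,
            elements=[ElementSpec(kind="orfan_like", name="e", length=1500,
                                  orf_aa=300, antisense_frac=0.0)],
        )
        contigs, truth = generate_virome(cfg)
        reads = simulate_reads(contigs, truth, cfg)
        assert reads and all(r.truth_strand == "sense" for r in reads)

    def test_read_longer_than_contig_rejected(self):
        cfg = SyntheticConfig(seed=9, n_host=1, host_len=(50, 60), elements=[])
        contigs, truth = generate_virome(cfg)
        with pytest.raises(ConfigError, match="read_len"):
            simulate_reads(contigs, truth, cfg)

    def test_hit_table_omits_exactly_orfan_elements(self, virome):
        contigs, truth = virome
        hits = emit_hit_table(truth)
        hit_ids = {h.query_id for h in hits}
        orfan_ids = {cid for cid, t in truth.contigs.items() if t.kind == "orfan_like"}
        assert hit_ids == set(truth.contigs) - orfan_ids
        assert orfan_ids == {"orfan1", "orfan2", "orfan3"}

    def test_all_host_fixture_every_contig_hit(self):
        cfg = SyntheticConfig(seed=2, n_host=4, elements=[])
        _, truth = generate_virome(cfg)
        assert {h.query_id for h in emit_hit_table(truth)} == set(truth.contigs)
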