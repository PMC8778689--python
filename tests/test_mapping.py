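import numpy as np
import pytest
from scipy import stats as sps

from viroscreen import mapping
from viroscreen.seqio import ReadRecord, SequenceRecord, reverse_complement
from viroscreen.synthetic import SyntheticConfig, generate_virome, simulate_reads


def nt(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestBuildIndex:
    def test_both_strands_indexed(self):
        contig = SequenceRecord(id="c", residues="ACGTACGT")
        index = mapping.build_index([contig], k=5)
        fwd = [km for km, v in index.entries.items() if ("c", "+") in v]
        rev = [km for km, v in index.entries.items() if ("c", "-") in v]
        assert len(fwd) >= 4 and len(rev) >= 4
        assert "ACGTA" in fwd
        assert reverse_complement("ACGTA") in rev

    def test_palindromic_kmer_carries_both_strands(self):
        contig = SequenceRecord(id="c", residues="AACGCGTTAA")
        index = mapping.build_index([contig], k=6)
        pal = "ACGCGT"
        assert pal == reverse_complement(pal)
        assert index.entries[pal] >= {("c", "+"), ("c", "-")}

    def test_empty_contig_list(self):
        index = mapping.build_index([], k=5)
        read = ReadRecord(id="r", residues="ACGTACGTAC")
        assert mapping.assign_read(index, read).status == "unassigned"

    def test_non_nucleotide_rejected(self):
        prot = SequenceRecord(id="p", residues="MKLV", alphabet="protein")
        with pytest.raises(TypeError):
            mapping.build_index([prot], k=3)


class TestAssignRead:
    @pytest.fixture()
    def index(self, rng):
        self.contig = SequenceRecord(id="C", residues=nt(rng, 500))
        return mapping.build_index([self.contig], k=21)

    def test_exact_substring_assigned_sense(self, index):
        read = ReadRecord(id="r", residues=self.contig.residues[100:200])
        a = mapping.assign_read(index, read)
        assert (a.status, a.contig_id, a.strand) == ("assigned", "C", "+")

    def test_reverse_complement_assigned_antisense(self, index):
        read = ReadRecord(id="r", residues=reverse_complement(self.contig.residues[100:200]))
        a = mapping.assign_read(index, read)
        assert (a.status, a.contig_id, a.strand) == ("assigned", "C", "-")

    def test_equal_fraction_tie_is_ambiguous(self, rng):
        shared = nt(rng, 120)
        c1 = SequenceRecord(id="c1", residues=shared + nt(rng, 100))
        c2 = SequenceRecord(id="c2", residues=shared + nt(rng, 100))
        index = mapping.build_index([c1, c2], k=21)
        read = ReadRecord(id="r", residues=shared[10:110])
        assert mapping.assign_read(index, read).status == "ambiguous"

    def test_read_shorter_than_k_unassigned_with_warning(self, index):
        short = ReadRecord(id="r", residues="ACGTACGT")
        with pytest.warns(UserWarning, match="shorter than k"):
            assert mapping.assign_read(index, short).status == "unassigned"

    def test_foreign_read_unassigned(self, index, rng):
        read = ReadRecord(id="r", residues=nt(rng, 100))
        assert mapping.assign_read(index, read).status == "unassigned"


class TestCountStrands:
    def test_exact_reads_counted_by_strand(self, rng):
        contig = SequenceRecord(id="C", residues=nt(rng, 1000))
        index = mapping.build_index([contig], k=21)
        reads = []
        for i in range(100):
            start = int(rng.integers(0, 900))
            reads.append(ReadRecord(id=f"s{i}", residues=contig.residues[start:start + 100]))
        for i in range(20):
            start = int(rng.integers(0, 900))
            reads.append(ReadRecord(
                id=f"a{i}",
                residues=reverse_complement(contig.residues[start:start + 100]),
            ))
        counts = mapping.count_strands(index, reads)
        cc = counts.get("C")
        assert (cc.n_sense, cc.n_antisense) == (100, 20)

    def test_no_reads_all_zero(self, rng):
        contig = SequenceRecord(id="C", residues=nt(rng, 200))
        counts = mapping.count_strands(mapping.build_index([contig]), [])
        assert counts.total_reads == 0
        assert counts.get("C").n_sense == 0

    def test_conservation_and_accuracy_on_fixture(self, pipeline_result):
        counts = pipeline_result.counts
        assert counts.n_assigned + counts.n_ambiguous + counts.n_unassigned == counts.total_reads
        # error-free exact-substring reads, k=21: every read assigned correctly
        assert counts.truth_accuracy == 1.0
        assert counts.n_unassigned == 0

    def test_strand_symmetry_under_read_reverse_complement(self, rng):
        contig = SequenceRecord(id="C", residues=nt(rng, 800))
        index = mapping.build_index([contig], k=21)
        reads = []
        for i in range(60):
            start = int(rng.integers(0, 700))
            frag = contig.residues[start:start + 100]
            if i % 3 == 0:
                frag = reverse_complement(frag)
            reads.append(ReadRecord(id=f"r{i}", residues=frag))
        flipped = [
            ReadRecord(id=r.id, residues=reverse_complement(r.residues)) for r in reads
        ]
        c1 = mapping.count_strands(index, reads).get("C")
        c2 = mapping.count_strands(index, flipped).get("C")
        assert (c1.n_sense, c1.n_antisense) == (c2.n_antisense, c2.n_sense)

    def test_antisense_fraction_recovered_within_binomial_ci(self):
        # one deep contig at antisense fraction 0.2; the empirical fraction
        # must fall in the central 99% interval of Binomial(n, 0.2)
        config = SyntheticConfig(
            seed=7, n_host=0, depth=2000.0,
            elements=[
                __import__("viroscreen").ElementSpec(
                    kind="orfan_like", name="deep", length=2000, orf_aa=300,
                    antisense_frac=0.2, has_known_relative=False,
                )
            ],
        )
        contigs, truth = generate_virome(config)
        reads = simulate_reads(contigs, truth, config)
        index = mapping.build_index(contigs, k=21)
        counts = mapping.count_strands(index, reads)
        cc = counts.get("deep")
        n = cc.n_sense + cc.n_antisense
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.2)
        assert lo <= cc.n_antisense <= hi

    def test_counts_tsv_roundtrip(self, tmp_path, rng):
        contig = SequenceRecord(id="C", residues=nt(rng, 400))
        index = mapping.build_index([contig], k=21)
        reads = [ReadRecord(id="r0", residues=contig.residues[10:110])]
        counts = mapping.count_strands(index, reads)
        mapping.write_counts(counts, tmp_path / "counts.tsv")
        back = mapping.read_counts(tmp_path / "counts.tsv")
        assert back.get("C").n_sense == 1
        assert back.total_reads == counts.total_reads
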