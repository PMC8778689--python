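# Methods

This note documents the models, procedures, parameter choices and known
limitations behind `viroscreen`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The replication-signature model

The screen rests on a simple strand-asymmetry model of RNA-seq read
orientation. An ordinary transcript is synthesised from one strand only;
reads derived from it map almost exclusively in sense orientation, with a
small antisense background from spurious antisense transcription and
library artefacts. A replicating viral RNA is copied through a
complementary strand (dsRNA replication intermediate), so a substantial
minority of reads map antisense. The screen therefore demands, for a
candidate contig:

* no homology hit at E ≤ `evalue_max` (default 10⁻⁵) — known genes and
  known viruses are handled elsewhere;
* length strictly greater than `min_contig_len` (default 1000 nt, a literal
  reading of "over 1 kb");
* a longest ORF of at least `min_protein_len` amino acids (default 150,
  ≈ 15 kDa; stop codon excluded). Protein mass is treated as a gloss on
  length, not an independent criterion;
* reads on **both** strands, and antisense/sense ratio ≥ `min_strand_ratio`
  (default 0.1). The ratio is a lower bound only: antisense-dominant
  contigs (ratio > 1) also pass.

Polarity is defined by the contig's longest ORF (sense = coding strand),
because assembler orientation is arbitrary; this makes the verdict
invariant under reverse-complementing the contig, which the suite tests.
The antisense ratio is undefined (and the contig fails) when the sense
count is zero. The 0.1 floor is exposed as a parameter because the
literature it encodes is a soft "around 1/10"; the default is used
throughout and never tuned per dataset.

A passed candidate may still be a transcribed host locus; the decisive
wet-lab follow-up (PCR on total nucleic acid vs cDNA) is outside a sequence
package, but its *decision logic* is kept: an optional per-contig
`dna_positive` annotation flags a candidate as genomic in origin and
removes it from the viral pool while leaving the sequence verdict intact.

## Orientation-aware read assignment

Instead of a general-purpose mapper, reads are assigned by an exact k-mer
voter with a fully specified contract: every k-mer of every contig is
indexed on both strands; a read is assigned to the (contig, strand) pair
matching the largest fraction of its k-mers if that fraction is at least
`min_frac` (default 0.5) and strictly exceeds the runner-up; exact ties are
ambiguous (and excluded from both strand counts, keeping the ratio
well-defined); weaker best matches are unassigned. Matching tolerates no
mismatches — tolerance comes from requiring only a fraction of k-mers.

Defaults: k = 21 and 100-nt single-end reads, so an error-free read
contributes 80 k-mers and random 4²¹ collisions are negligible at desk
scale; with an odd k no k-mer equals its own reverse complement (palindromic
even-k k-mers are indexed on both strands and can never decide orientation
alone). Paired input can be handled by mapping mates independently and
flipping the mate-2 strand (FR convention); the generator emits single-end
reads. Gapped alignment, base qualities and multi-mapping resolution beyond
the tie rule are out of scope.

## ORF prediction and genetic codes

`find_orfs` reports every complete ORF (ATG through in-frame stop, nested
ATGs included) on both strands and all three frames, under NCBI translation
table 1 ("standard") or table 4 ("mold mitochondrial", UGA = Trp — the
standard choice for fungal mitoviruses, which are translated by the
mitochondrial apparatus). Near-cognate starts are not considered.
Equivalence with a brute-force oracle (enumerate every ATG, scan to the
next in-frame stop) is property-tested on random sequences under both
codes. `maximal_orfs` reduces the nested set to the longest ORF per
(strand, stop) — the "major ORFs" view used when reporting genome layouts.
Coordinates are 1-based, inclusive, on the forward strand of the stored
sequence; internal-stop positions are 1-based within the analysed region.

Slippage detection is purely coordinate-based: the intersection of two
same-strand ORFs, reported with its sequence in the RNA alphabet (stored
sequences are DNA-alphabet; only display is RNA) and the downstream-minus-
upstream frame difference mapped to −1/0/+1. The bicistronic totivirus
layout produces a 4-nt AUGA overlap at a −1 shift: the CP stop (UGA) and
the RdRp initiator (AUG) share three bases.

## RdRp motifs and the toxin checklist

Mitochondrial-virus RdRps carry six conserved motifs (I–VI) with the GDD
catalytic triad in motif IV. No formal patterns exist for these motifs in
the literature this package encodes, so it ships package-curated degenerate
regular expressions (`data/rdrp_motifs.json`, editable data rather than
code), constructed so that motif IV contains the GDD core and false-match
rates in random protein are small (each pattern constrains ~5 positions).
GDD itself is an exact search with all occurrences reported; each consensus
motif reports at most its first match, and `motif_series_complete` checks
the full collinear series. These patterns are calibrated to the synthetic
generator's planted instances; on real RdRps they should be re-derived from
an alignment of the relevant clade — which is exactly why they ship as
data.

The K2-type preprotoxin checklist is positional: mean Kyte–Doolittle
hydropathy > 0 over aa 27–45 (the N-terminal membrane-interacting stretch);
N-X-[S/T] sequons with X ≠ P at the first three positions of the 4-aa
windows 177–180, 214–217 and 261–264; and the dibasic KR sites at 220–221
(KEX1) and 267–268 (KEX2) whose cleavage matures the toxin — a failed site
names the observed dipeptide, and substitutions are listed against a
supplied reference. Windows beyond the protein's length are reported
"not evaluable" rather than failed.

## Alignment and identity

Identity is the p-distance convention: 100 · identical / compared over the
columns of a global pairwise alignment, excluding every gap-containing
column (pairwise deletion). Alignments come from an affine-gap
Needleman–Wunsch with an explicit cost model (a gap of length g costs
open + (g−1)·extend; gap states open only from the match state) and a
deterministic traceback (ties: diagonal, then up, then left). Scores are
property-tested against exhaustive enumeration of all alignments for short
strings and cross-checked against an independent aligner's optimal scores.

Scoring defaults: nucleotide match +2 / mismatch −3 / gap open −12 /
extend −6; protein BLOSUM62 with −11/−1. The stiff nucleotide gap penalties
are a deliberate design choice: with soft penalties (e.g. −5/−2) the
optimal alignment of a divergent substitution-only pair buys back mismatch
clusters with compensating gap pairs, and because gapped columns are
excluded from the p-distance this *inflates* apparent identity — measured
at up to +4.8 points at 70% identity and +2.1 at 77.6% on 1.2-kb pairs.
With −12/−6 such pairs align gap-free and planted identities in the 70–99%
range are recovered to within ≈ 0.05 points; the suite asserts ±1. The
stiff regime mirrors the DNA gap defaults of the classic multiple-alignment
tools on whose alignments published p-distance identities are computed.

Matrices report one decimal place (the precision at which such identities
are published); pairwise statistics keep full precision. Pairwise global
alignment stands in for multiple alignment — equivalent in practice for
same-amplicon fragment sets, which is the use here; trimming to a shared
region is explicit coordinate extraction (`trim=(start, end)`), never
automatic. Memory grows as 3·n·m float32 cells, comfortable to a few kb per
sequence; Kimura-style model-corrected distances and phylogenies are out of
scope.

## Demarcation rules and infection summaries

The rule engine applies percent-identity thresholds shipped as data
(`data/demarcation_rules.tsv`): narnavirus 50% and mitovirus 40% RdRp aa
identity for species; totivirus 50% aa (applied to both CP and RdRp
markers); partitivirus species at 80% CP / 90% RdRp aa and genera below 24%
RdRp aa. "Below" is strict (<); at or above any species threshold the
candidate is a variant of the known species; otherwise below a genus bound
it is a new-genus candidate, else a new-species candidate; with no
applicable rules the verdict is unresolved. Verdicts are monotone in
identity and are *candidate labels citing their rule*, never authoritative
taxonomy. Host specificity — part of the totivirus criteria — is carried as
metadata and reported, but never decides a verdict: it is not computable
from sequence. Genus aliases fold onto the scope whose rules govern them
(cryspovirus → partitivirus).

Infection tables map strains to per-virus detections ("isolate(ct)" cells,
Ct = real-time PCR threshold cycle on cDNA). A strain is infected with ≥ 1
detection and mixed with ≥ 2 distinct virus columns — a helper totivirus
plus its satellite counts as mixed, since the columns are distinct
replicating elements. Uninfected strains may be absent from the table; the
strain total is supplied separately (default 24, the shipped fixture's
panel size). The shipped fixture transcribes a published 24-strain
detection table; where a cell printed two threshold cycles (the bipartite
cryspovirus), the fixture carries the RNA1 cycle so each cell is one
token — counts are unaffected.

## The synthetic virome generator

The generator emulates the data-generating process the screen assumes, not
real library chemistry. Per contig, reads are single-end, error-free by
default (`error_rate` exists for robustness experiments), drawn
Poisson(depth) in number at uniform start positions, each antisense with
the contig's antisense fraction and tagged with its truth strand. Host
contigs are uniform-random sequence with antisense fraction 0.005 — not
exactly 0, so the both-strands rule (not only the ratio rule) is exercised;
viral elements default to 0.2, a substantial replication signature well
separated from host noise. Read length 100 nt and mean depth 300
reads/contig are desk-scale choices that keep the default end-to-end run in
seconds while leaving binomial fluctuations far from the decision
boundaries; the strand-fraction recovery check uses depth 2000.

Element architectures are built codon-aware: coding regions are
reverse-translated with random synonymous codons, so the only in-frame
stops are planted ones, and UTRs are sampled free of ATG and CAT
trinucleotides so no ORF can initiate in (or extend through) them on either
strand. Defaults reproduce the target system's coordinates: a 5878-nt
bicistronic element with a 942-aa CP ORF and an 882-aa RdRp ORF overlapping
by the AUGA tetranucleotide at nt 3166–3169 in the −1 frame (the last two
CP codons are pinned so the RdRp frame carries a stop immediately upstream
of its AUG, keeping the maximal RdRp ORF at exactly the planted length); a
2495-nt narnavirus-like element (829-aa RdRp); a 2465-nt mitovirus-like
element (714-aa RdRp, mold-mitochondrial code, two internal UGA-Trp codons
so the standard code splits the ORF, motifs I–VI planted collinearly with
GDD in motif IV); a bipartite partitivirus-like pair (1689 + 1321 nt); a
1165-nt satellite with a 362-aa preprotoxin carrying all six checklist
features (optionally a planted premature stop, e.g. at ORF nt 232); and
ORFan elements (1404/1875/2637 nt) with no database relative. Every element
is verified against its own planted truth before emission and re-drawn on
the rare chance collision (e.g. a spurious upstream motif match in random
filler, ~4% per mitovirus-like draw); generation is deterministic per seed,
and identical config + seed gives byte-identical FASTA/FASTQ/manifest
output.

`mutate_to_identity` plants pairwise identities exactly: round((100−t)·L/100)
positions sampled without replacement, each substituted to a different
residue; targets below the alphabet noise floor (25% nt, 5% protein) are
rejected. The synthetic hit table gives one strong hit (E = 10⁻⁵⁰) to every
host contig and every element with a known relative, and none to ORFan
elements — deliberately documenting the screen's blind spot: a genuine
virus with no database relative enters the ORFan pool, and a virus *with*
a relative never does.

What passing these tests shows — and does not. The fixtures have error-free
reads, uniform coverage, no chimeras, no indels and well-separated strand
fractions, so recovery results certify the *filter logic and its
thresholds*, not mapper sensitivity on noisy data or assembler behaviour.
On real data the antisense fraction of a replicating element varies with
replication stage and library protocol; the 0.1 floor, k, and `min_frac`
are the knobs to revisit, and the homology step depends entirely on the
external search whose hit table is this package's input.

## Deposited-record checks

The published quantities this package is organised around (ORF sizes
942/882/714 aa, the AUGA overlap at nt 3166–3169, the internal stop at
232–234, identities 97.7 / 94.75 / 96.1%, range minima 77.6 and 95.5%)
are recomputable from the study's deposited GenBank records with
`viroscreen.accessions.run_accession_checks`, given a local directory of
those records as FASTA (they are GenBank data and do not ship with the
package; see `data/accessions/README.md`). The corresponding test fails
with an explanatory message until the records are provided. The synthetic
architectures above are stand-ins built to the same coordinates and are
always exercised.

## Numerical and degenerate-input conventions

Nucleotide U normalises to T on input; RNA alphabet appears only in
display fields. Empty FASTA files parse to empty lists with a warning;
sequence before the first header, FASTQ length mismatches and unparseable
table cells raise `FormatError` naming the offence (and line, for tables).
Hit tables are the 12-column tab-separated dialect; extra columns are
ignored with a warning, and filtering is monotone in the E-value cutoff.
ORF-less contigs get `orf_ok = false` and default + orientation; contigs
with zero assigned reads fail the both-strands rule with an undefined
ratio. Reads shorter than k are unassigned with a warning. float32 DP
matrices hold exact integer-valued scores at these magnitudes; traceback
state selection uses a 10⁻³ tolerance against them.
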