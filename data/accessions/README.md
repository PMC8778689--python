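# Deposited GenBank records (drop-in directory)

The accession-based checks (`viroscreen.accessions.run_accession_checks`,
exercised by `tests/test_acceptance.py::test_deposited_record_checks`)
recompute published ORF sizes, the slippage overlap, a premature-stop
position, pairwise identities and identity-range minima from the deposited
GenBank records of the study system. Those records are GenBank data and do
not ship with this package.

To enable the checks, download each accession as FASTA into this directory,
one record per file, named `<accession>.fasta` (plain or gzipped), e.g.

```
data/accessions/OK412910.fasta
data/accessions/AF039063.fasta
```

Required accessions: OK377006–OK377025, OK412909–OK412912, OK412915,
OK412916, AF039063, U01060 (see
`viroscreen.accessions.ACCESSION_GROUPS` for the grouping).
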