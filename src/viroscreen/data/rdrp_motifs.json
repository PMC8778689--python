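{
  "description": "Degenerate consensus patterns for the six conserved motifs (I-VI) of mitochondrial-virus RdRps, as regular expressions over the amino-acid alphabet. Package-curated from the conserved columns of published mitovirus RdRp alignments; motif IV carries the hallmark GDD catalytic core. Editable: the scanner loads whatever patterns this file holds.",
  "motifs": {
    "I": "[KR].[DE][LIVM].[FYW]G",
    "II": "G[LIVM][ST].{2}[DE]P",
    "III": "[DE].{2}[FYW][ST]G[LIVM]",
    "IV": "[SG][LIVM].GDD[LIVMFY]",
    "V": "[KR][LIVM].{2}[FYW][DE]G",
    "VI": "[DE][FYW][KR].{2}G[ST]"
  }
}
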