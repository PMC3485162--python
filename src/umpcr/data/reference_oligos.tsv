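# Published UM-PCR maize panel: adapters, SSR primers, and adapter-primer
# (U- universal, C- common) variants, with the melting temperatures reported
# alongside the original panel (tm_reported, °C).
# formula_concordant = 1 where tm_reported equals the calibrated formula
#   Tm = 62.30 + 0.41*(%GC) - 500/N  (half-up, 2 decimals).
# Three reported values are internally inconsistent with their sequences:
# phi120-F and phi120-R (61.92/61.95) are transposed relative to their
# sequences, and C-umc1268-F (reported 71.93) matches no integer GC count at
# 43 nt (formula gives 72.60); these rows are flagged 0.
name	role	tail_length	sequence	tm_reported	formula_concordant
universal adapter-F	adapter	0	CTCGTAGACTGCGTACCA	57.30	1
universal adapter-R	adapter	0	TACTCAGGACTCATCGTC	55.02	1
common adapter	adapter	0	CCTTCCTTCCTTCCCCCC	61.86	1
phi085-F	ssr_primer	0	AGCAGAACGGCAAGGGCTACT	61.92	1
phi085-R	ssr_primer	0	TTTGGCACACCACGACGA	57.30	1
U-phi085-F	adapter_primer	18	CTCGTAGACTGCGTACCAAGCAGAACGGCAAGGGCTACT	72.61	1
U-phi085-R	adapter_primer	18	TACTCAGGACTCATCGTCTTTGGCACACCACGACGA	70.05	1
C-phi085-F	adapter_primer	18	CCTTCCTTCCTTCCCCCCAGCAGAACGGCAAGGGCTACT	74.71	1
C-phi085-R	adapter_primer	18	CCTTCCTTCCTTCCCCCCTTTGGCACACCACGACGA	73.47	1
phi041-F	ssr_primer	0	TTGGCTCCCAGCGCCGCAAA	63.95	1
phi041-R	ssr_primer	0	GATCCAGAGCGATTTGACGGCA	61.94	1
U-phi041-F	adapter_primer	18	CTCGTAGACTGCGTACCATTGGCTCCCAGCGCCGCAAA	73.96	1
U-phi041-R	adapter_primer	18	TACTCAGGACTCATCGTCGATCCAGAGCGATTTGACGGCA	71.33	1
C-phi041-F	adapter_primer	18	CCTTCCTTCCTTCCCCCCTTGGCTCCCAGCGCCGCAAA	76.12	1
C-phi041-R	adapter_primer	18	CCTTCCTTCCTTCCCCCCGATCCAGAGCGATTTGACGGCA	74.40	1
phi123-F	ssr_primer	0	GGAGACGAGGTGCTACTTCTTCAA	61.97	1
phi123-R	ssr_primer	0	TGTGGCTGAGGCTAGGAATCTC	61.94	1
U-phi123-F	adapter_primer	18	CTCGTAGACTGCGTACCAGGAGACGAGGTGCTACTTCTTCAA	71.87	1
U-phi123-R	adapter_primer	18	TACTCAGGACTCATCGTCTGTGGCTGAGGCTAGGAATCTC	71.33	1
C-phi123-F	adapter_primer	18	CCTTCCTTCCTTCCCCCCGGAGACGAGGTGCTACTTCTTCAA	73.82	1
C-phi123-R	adapter_primer	18	CCTTCCTTCCTTCCCCCCTGTGGCTGAGGCTAGGAATCTC	74.40	1
umc1478-F	ssr_primer	0	GAAGCTTCTCCTCTCGCGTCTC	63.80	1
umc1478-R	ssr_primer	0	CAGTCCCAGACCCTAGCTCAGTC	65.52	1
U-umc1478-F	adapter_primer	18	CTCGTAGACTGCGTACCAGAAGCTTCTCCTCTCGCGTCTC	73.38	1
U-umc1478-R	adapter_primer	18	TACTCAGGACTCATCGTCCAGTCCCAGACCCTAGCTCAGTC	73.10	1
C-umc1478-F	adapter_primer	18	CCTTCCTTCCTTCCCCCCGAAGCTTCTCCTCTCGCGTCTC	75.43	1
C-umc1478-R	adapter_primer	18	CCTTCCTTCCTTCCCCCCCAGTCCCAGACCCTAGCTCAGTC	76.10	1
umc1268-F	ssr_primer	0	ACGAACAACCTAGCACAGTCCTAAA	60.34	1
umc1268-R	ssr_primer	0	CAAGGCGGTTACCAAGTTTACATC	60.26	1
U-umc1268-F	adapter_primer	18	CTCGTAGACTGCGTACCAACGAACAACCTAGCACAGTCCTAAA	70.70	1
U-umc1268-R	adapter_primer	18	TACTCAGGACTCATCGTCCAAGGCGGTTACCAAGTTTACATC	69.92	1
C-umc1268-F	adapter_primer	18	CCTTCCTTCCTTCCCCCCACGAACAACCTAGCACAGTCCTAAA	71.93	0
C-umc1268-R	adapter_primer	18	CCTTCCTTCCTTCCCCCCCAAGGCGGTTACCAAGTTTACATC	72.85	1
phi120-F	ssr_primer	0	TGATGTCCCAGCTCTGAACTGAC	61.92	0
phi120-R	ssr_primer	0	GACTCTCACGGCGAGGTATGA	61.95	0
U-phi120-F	adapter_primer	18	CTCGTAGACTGCGTACCATGATGTCCCAGCTCTGAACTGAC	72.10	1
U-phi120-R	adapter_primer	18	TACTCAGGACTCATCGTCGACTCTCACGGCGAGGTATGA	71.56	1
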