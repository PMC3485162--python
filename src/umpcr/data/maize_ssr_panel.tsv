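# Published UM-PCR maize SSR panel (six loci; the quintuple assay uses the
# first five). Adapters are declared in the config block and attached to the
# 5' end of the forward (adapter-F) and reverse (adapter-R) primers.
#@ adapter_f = CTCGTAGACTGCGTACCA
#@ adapter_r = TACTCAGGACTCATCGTC
locus	forward	reverse	conc_factor
phi085	AGCAGAACGGCAAGGGCTACT	TTTGGCACACCACGACGA	2.0
phi041	TTGGCTCCCAGCGCCGCAAA	GATCCAGAGCGATTTGACGGCA	1.0
phi123	GGAGACGAGGTGCTACTTCTTCAA	TGTGGCTGAGGCTAGGAATCTC	1.0
umc1478	GAAGCTTCTCCTCTCGCGTCTC	CAGTCCCAGACCCTAGCTCAGTC	1.0
umc1268	ACGAACAACCTAGCACAGTCCTAAA	CAAGGCGGTTACCAAGTTTACATC	1.0
phi120	TGATGTCCCAGCTCTGAACTGAC	GACTCTCACGGCGAGGTATGA	1.0
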