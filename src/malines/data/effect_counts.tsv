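consequence	YoungT1	PeakT2	OldT5
downstream_gene_variant	18	4	18
intergenic_variant	0	0	1
intron_variant	2	1	2
missense_variant	3	2	4
splice_donor_variant	1	0	0
stop_gained	1	0	0
synonymous_variant	1	1	6
upstream_gene_variant	19	3	16
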