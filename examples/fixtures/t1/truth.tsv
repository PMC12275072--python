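peak_name	gene_symbol	elem_chrom	elem_start	elem_end	distance	significant
P1	G1	chrT	46000	46500	53750	True
P2	G1	chrT	99000	99400	800	True
P3	G2	chrT	502000	502300	202150	True
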