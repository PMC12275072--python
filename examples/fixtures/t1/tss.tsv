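gene_symbol	entrez_id	chrom	tss	strand
G1	1001	chrT	100000	+
G2	1002	chrT	300000	-
G3	1003	chrT	900000	+
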