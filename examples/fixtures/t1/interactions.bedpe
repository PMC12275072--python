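chrT	45000	50000	chrT	100000	105000	12.0
chrT	500000	505000	chrT	295000	300000	8.0
chrT	600000	605000	chrT	700000	705000	3.0
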