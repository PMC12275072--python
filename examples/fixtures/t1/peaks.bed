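chrT	46000	46500	P1
chrT	99000	99400	P2
chrT	502000	502300	P3
chrT	700000	700200	P4
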