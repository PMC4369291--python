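minmol 1 2 1
C	0.0000	0.0000	0	0	.
N	1.5000	0.0000	1	0	.
1	2	1	F
end minmol
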