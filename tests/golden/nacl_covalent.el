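minmol 1 2 1
Na	0.0000	0.0000	0	0	.
Cl	1.5000	0.0000	0	0	.
1	2	1	F
end minmol
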