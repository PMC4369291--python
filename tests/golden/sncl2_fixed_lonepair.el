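minmol 1 3 2
Sn	0.0000	0.0000	0	2	.
Cl	-1.2990	-0.7500	0	0	.
Cl	1.2990	-0.7500	0	0	.
1	2	1	F
1	3	1	F
end minmol
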