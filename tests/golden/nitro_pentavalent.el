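minmol 1 4 3
C	0.0000	0.0000	0	0	.
N	1.5000	0.0000	0	0	.
O	2.6250	1.1000	0	0	.
O	2.6250	-1.1000	0	0	.
1	2	1	F
2	3	2	F
2	4	2	F
end minmol
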