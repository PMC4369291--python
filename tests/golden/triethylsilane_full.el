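minmol 1 7 6
Si	0.0000	0.0000	0	0	1
C	0.0000	1.5000	0	0	.
C	0.0000	3.0000	0	0	.
C	-1.2990	-0.7500	0	0	.
C	-2.5981	-1.5000	0	0	.
C	1.2990	-0.7500	0	0	.
C	2.5981	-1.5000	0	0	.
1	2	1	F
2	3	1	F
1	4	1	F
4	5	1	F
1	6	1	F
6	7	1	F
end minmol
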