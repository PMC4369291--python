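minmol 1 7 7
C	0.0000	1.5000	0	0	.
C	-1.2990	0.7500	0	0	.
C	-1.2990	-0.7500	0	0	.
C	-0.0000	-1.5000	0	0	.
C	1.2990	-0.7500	0	0	.
C	1.2990	0.7500	0	0	.
Br	0.0000	3.0000	0	0	.
1	2	2	F
2	3	1	F
3	4	2	F
4	5	1	F
5	6	2	F
6	1	1	F
1	7	1	F
end minmol
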