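minmol 1 5 5
C	0.0000	1.2760	0	0	.
C	-1.2135	0.3943	0	0	.
C	-0.7500	-1.0323	0	0	.
C	0.7500	-1.0323	0	0	.
C	1.2135	0.3943	0	0	.
1	2	1	F
2	3	1	F
3	4	1	F
4	5	1	F
5	1	1	F
end minmol
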