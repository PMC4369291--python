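minmol 1 6 5
C	0.0000	0.0000	0	0	.
C	0.0000	1.5000	0	0	.
C	-1.4266	0.4635	0	0	.
C	-0.8817	-1.2135	0	0	.
C	0.8817	-1.2135	0	0	.
C	1.4266	0.4635	0	0	.
1	2	1	F
1	3	1	F
1	4	1	F
1	5	1	F
1	6	1	F
end minmol
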