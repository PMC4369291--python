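minmol 1 18 19
Fe	-1.2000	0.0000	0	0	.
C	-3.2000	3.8760	0	0	.
C	-4.4135	2.9943	0	0	.
C	-3.9500	1.5677	0	0	.
C	-2.4500	1.5677	0	0	.
C	-1.9865	2.9943	0	0	.
C	-3.2000	2.6000	0	0	.
CO	-2.4000	-1.8000	0	0	.
Fe	1.2000	0.0000	0	0	.
C	3.2000	3.8760	0	0	.
C	1.9865	2.9943	0	0	.
C	2.4500	1.5677	0	0	.
C	3.9500	1.5677	0	0	.
C	4.4135	2.9943	0	0	.
C	3.2000	2.6000	0	0	.
OC	2.4000	-1.8000	0	0	.
C	0.0000	0.9000	0	0	.
C	0.0000	-0.9000	0	0	.
2	3	1	F
3	4	1	F
4	5	1	F
5	6	1	F
6	2	1	F
1	7	1	I
1	8	1	F
10	11	1	F
11	12	1	F
12	13	1	F
13	14	1	F
14	10	1	F
9	15	1	F
9	16	1	F
1	17	2	F
9	17	1	F
1	18	1	F
9	18	2	F
1	9	1	F
end minmol
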