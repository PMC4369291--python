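minmol 1 20 29
Fe	-1.2000	0.0000	0	0	.
C	-3.2000	3.4760	0	0	.
C	-4.4135	2.5943	0	0	.
C	-3.9500	1.1677	0	0	.
C	-2.4500	1.1677	0	0	.
C	-1.9865	2.5943	0	1	.
C	-2.2000	-1.6000	0	2	.
O	-3.2000	-2.7000	0	0	.
C	-3.0000	-2.5000	0	2	.
O	-4.0000	-3.6000	0	0	.
Fe	1.2000	0.0000	0	0	.
C	3.2000	3.4760	0	0	.
C	1.9865	2.5943	0	0	.
C	2.4500	1.1677	0	0	.
C	3.9500	1.1677	0	0	.
C	4.4135	2.5943	0	1	.
C	2.2000	-1.6000	0	2	.
O	3.2000	-2.7000	0	0	.
C	3.0000	-2.5000	0	2	.
O	4.0000	-3.6000	0	0	.
2	3	2	F
3	4	1	F
4	5	2	F
5	6	1	F
6	2	1	F
1	2	0	F
1	3	0	F
1	4	0	F
1	5	0	F
1	6	0	F
7	8	2	F
1	7	0	F
9	10	2	F
1	9	0	F
12	13	2	F
13	14	1	F
14	15	2	F
15	16	1	F
16	12	1	F
11	12	0	F
11	13	0	F
11	14	0	F
11	15	0	F
11	16	0	F
17	18	2	F
11	17	0	F
19	20	2	F
11	19	0	F
1	11	1	F
end minmol
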