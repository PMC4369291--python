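minmol 1 6 4
N	0.0000	0.0000	1	0	.
H	1.0607	1.0607	0	0	.	i2
H	-1.0607	1.0607	0	0	.	i2
H	-1.0607	-1.0607	0	0	.	i2
H	1.0607	-1.0607	0	0	.	i2
Br	4.5000	0.0000	-1	0	.
1	2	1	F
1	3	1	F
1	4	1	F
1	5	1	F
end minmol
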