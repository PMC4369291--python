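minmol 1 4 3
Si	0.0000	0.0000	0	0	1
Et	0.0000	1.5000	0	0	.	aminmol 1 3 2\nC\t0.0000\t0.0000\t0\t0\t.\nC\t1.2990\t0.7500\t0\t0\t.\n*\t2.5981\t0.0000\t0\t0\t.\n1\t2\t1\tF\n2\t3\t1\tF\nend minmol\n
Et	-1.2990	-0.7500	0	0	.	aminmol 1 3 2\nC\t0.0000\t0.0000\t0\t0\t.\nC\t1.2990\t0.7500\t0\t0\t.\n*\t2.5981\t0.0000\t0\t0\t.\n1\t2\t1\tF\n2\t3\t1\tF\nend minmol\n
Et	1.2990	-0.7500	0	0	.	aminmol 1 3 2\nC\t0.0000\t0.0000\t0\t0\t.\nC\t1.2990\t0.7500\t0\t0\t.\n*\t2.5981\t0.0000\t0\t0\t.\n1\t2\t1\tF\n2\t3\t1\tF\nend minmol\n
1	2	1	F
1	3	1	F
1	4	1	F
end minmol
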