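minmol 1 2 1
Ph	0.0000	0.0000	0	0	.	aminmol 1 7 7\nC\t0.0000\t1.5000\t0\t0\t.\nC\t-1.2990\t0.7500\t0\t0\t.\nC\t-1.2990\t-0.7500\t0\t0\t.\nC\t-0.0000\t-1.5000\t0\t0\t.\nC\t1.2990\t-0.7500\t0\t0\t.\nC\t1.2990\t0.7500\t0\t0\t.\n*\t0.0000\t3.0000\t0\t0\t.\n1\t2\t2\tF\n2\t3\t1\tF\n3\t4\t2\tF\n4\t5\t1\tF\n5\t6\t2\tF\n6\t1\t1\tF\n1\t7\t1\tF\nend minmol\n
Br	1.5000	0.0000	0	0	.
1	2	1	F
end minmol
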