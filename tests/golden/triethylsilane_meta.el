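minmol 1 1 0
SiHEt3	0.0000	0.0000	0	0	.	aminmol 1 5 4\nSi\t0.0000\t0.0000\t0\t0\t1\nEt\t0.0000\t1.5000\t0\t0\t.\taminmol 1 3 2\\nC\\t0.0000\\t0.0000\\t0\\t0\\t.\\nC\\t1.2990\\t0.7500\\t0\\t0\\t.\\n*\\t2.5981\\t0.0000\\t0\\t0\\t.\\n1\\t2\\t1\\tF\\n2\\t3\\t1\\tF\\nend minmol\\n\nEt\t-1.2990\t-0.7500\t0\t0\t.\taminmol 1 3 2\\nC\\t0.0000\\t0.0000\\t0\\t0\\t.\\nC\\t1.2990\\t0.7500\\t0\\t0\\t.\\n*\\t2.5981\\t0.0000\\t0\\t0\\t.\\n1\\t2\\t1\\tF\\n2\\t3\\t1\\tF\\nend minmol\\n\nEt\t1.2990\t-0.7500\t0\t0\t.\taminmol 1 3 2\\nC\\t0.0000\\t0.0000\\t0\\t0\\t.\\nC\\t1.2990\\t0.7500\\t0\\t0\\t.\\n*\\t2.5981\\t0.0000\\t0\\t0\\t.\\n1\\t2\\t1\\tF\\n2\\t3\\t1\\tF\\nend minmol\\n\n*\t0.0000\t-1.5000\t0\t0\t.\n1\t2\t1\tF\n1\t3\t1\tF\n1\t4\t1\tF\n1\t5\t0\tF\nend minmol\n
end minmol
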