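primer_set	gene	genbank	forward_5p3p	reverse_5p3p
A	rps18	BX296557	TCGCTAGTTGGCATCGTTTATG	CGGAGGTTCGAAGACGATCA
A	ghra	BC134903	TCCTCCTTCATCGCTGCCTAT	GCAAAGGCTGATAGAAAGGAAACA
A	ghrb	EU649775	CAGAAGGCAGCAGCGAAGAC	CGGTGTTGGCTAAGCAGTCAGA
A	igf1ra	AF400275	GTTTGACGAGACGCAGCCTTAC	CAAAGGGAGGAGGGAAATGTGT
A	igf1rb	AF400276	CGGATGCGTCGGATGTGTGT	GTCTGGCGGAAATAACAAATGAGT
A	igf1	BC114262	CGAGCACAACGACACACAGATATT	CCAGTCTTTCTTTCTTCCCCTCTT
A	ztor	DQ666026	GCCATTCAGATCATCAACCGAGT	GCGATGCCGATTCCCACTCT
A	foxo5	AF114262	GCTGTTAGTCTGAATCCTGTGGGA	GCAGACAGCAAACTTGGCAAA
A	pgc1a	AY998087	TGAGGAAAATGAGGCCAACT	AGCTTCTTCAGCAGGGAAGG
B	rps18	AY099517	TGAGGTTGAGAGGGTGGTGACTA	CCTTCTGTCTGTTCAGGAACCAGT
B	stnnc	BC071546	GCAAGATCGACTACGACGAGTTCT	AGGCAGCATTGGTTCAGGGA
B	smyhc1	AY921649	GAGCCGTGATTCAGGACCCA	TGGCTTCACAACAAACAAACTCGT
B	tnni2	AF425744	GGTATGGACGGCAGGAAGAAGA	GGAACGGGAGGTTTACAGGACAG
B	myhz2	BC071279	GCCTGAGCTGATTGAAATGACGC	GCTCCTCACGCTGCTTCTGCTT
B	mstnb	AF540956	AGACCGCTGTGGCTGCTCAT	GGTAATGTATGGTGGGTGGTGGA
B	myog	AF202639	AGTGGACAGCATAACGGGAACAG	GCTGGTCTGAAGGTAACGGTGAG
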