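target	name	role	sequence	dye	quencher	use
L_brunnea	BruCo5F	forward	GGGGTTTTAGGGTTTGTGGTA			both
L_brunnea	BruCo5R	reverse	AATGTCGCCAACCATCTAAAG			both
L_brunnea	BruCo6F	forward	TTTATGCGATAGGAGCGATTG			single
L_brunnea	BruCo6R	reverse	CATCCAACCCGACAGTAAACA			single
L_brunnea	BruCo5P	probe	TGTTTACTGTCGGGTTGGATGTGGA	HEX	ZEN-IABkFQ	qpcr
L_bostrychophila	BosCo7F	forward	CGATCCCTACCGGAGTTAAAG			endpoint
L_bostrychophila	BosCo7R	reverse	TGGGCAACAACATAGTATCTATCG			endpoint
L_bostrychophila	BosCo8F	forward	ATGCTCTCAATCGGAGCTCTAG			qpcr
L_bostrychophila	BosCo8R	reverse	ACTTTAACTCCGGTAGGGATCG			qpcr
L_bostrychophila	BosCo9F	forward	TGGGCTAATCTCTCACATCATCT			single
L_bostrychophila	BosCo8P	probe	GGGCATGGATGTGGATAGACGAGC	Cy5	BHQ2	qpcr
L_decolor	DecCo10F	forward	CCGGCTTTTGGTATTATTTCAC			single
L_decolor	DecCo10R	reverse	ATTATCCCCATTACCCCAAA			single
L_decolor	DecCo11F	forward	CGAGCTTATTTTACTTCTGCGACT			both
L_decolor	DecCo11R	reverse	TGATCCATACAACGTAGCTAGTCA			both
L_decolor	DecCo11P	probe	TGCTGTTCCTACAGGAATCAAGGTTTT	6-FAM	BHQ2	qpcr
L_obscura	ObsCo12F	forward	GGACAGGGTGGACGGTTTATC			qpcr
L_obscura	ObsCo12R	reverse	CTGATTCCTGCTAAATGAAGAGAG			qpcr
L_obscura	ObsCo13F	forward	AGCTATTGCTCACGGAGGATA			endpoint
L_obscura	ObsCo13R	reverse	CCAATTGCGGACATAGCATAA			endpoint
L_obscura	ObsCo12P	probe	CCTCAGCTATTGCTCACGGAGGA	6-ROXN	BHQ2	qpcr
L_pearmani	PeaCo14F	forward	CTGACTTTTTCCCCCTTCACT			qpcr
L_pearmani	PeaCo14R	reverse	GCCAGGGTGTGAGATTCTAAA			both
L_pearmani	PeaCo15F	forward	TGGTGTGTGAGCAGGTATGGT			endpoint
L_pearmani	PeaCo14P	probe	AGGGAGTCGGAACCGGGTGAA	Quasar705	BHQ3	qpcr
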