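id	protein_a	pos_a	aa_a	protein_b	pos_b	aa_b	linker	evidence_count	ca_dist_reference
xl01	NID1	948	K	NID1	953	K	BS2G	1	10.4
xl02	NID1	1128	K	NID1	1165	K	BS2G	1	13.3
xl03	NID1	1072	K	NID1	1128	K	BS2G	1	16.7
xl04	NID1	948	K	NID1	1144	K	BS2G	1	17.9
xl05	LAMC1	850	K	NID1	1072	K	BS2G	1	20.9
xl06	NID1	948	K	NID1	1152	K	BS2G	1	22.2
xl07	NID1	1032	K	NID1	1072	K	BS2G	1	27.1
xl08	NID1	961	K	NID1	1072	K	BS2G	1	28.7
xl09	LAMC1	864	K	NID1	1152	K	BS2G	1	32.2
xl10	LAMC1	850	K	NID1	953	K	BS2G	1	33.0
xl11	NID1	1032	K	NID1	1152	K	BS2G	1	35.8
xl12	NID1	990	z	NID1	1038	R	photo-Leu	1	24.7
xl13	LAMC1	844	z	NID1	1072	K	photo-Leu	1	33.8
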