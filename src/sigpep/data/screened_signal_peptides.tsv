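id	sequence	annotation	secretion	length	net_charge	hydrophobicity_pct	axa_motif	tm_helix
LP_23790	MKKFNFKTMLLLVLASCVFGVVVNVTTSLGPQTTITAQA|SK	transglycosylase	with	39	3	59	1	1
LP_08330	MIKLRQVLKKILIVLMVFVLVFTAFSSSVDTVSA|HR	hypothetical protein	with	34	4	65	0	1
LP_04240	MKKLMCLFGVIGGLVFMSWTSPSIQATA|TN	cell surface protein	with	28	2	68	1	1
LP_23670	MQLLKRIMVIVGTLILGLQVSSVSGLA|AS	cell surface protein	with	27	2	70	0	1
LP_28190	MKRLRHIKLGMLLLSCLAFISMLAITSQA|AA	extracellular protein	with	29	4	62	0	1
LP_29340	MRKWQVAVVMLLAALGSWFAIGTQAQA|KT	glutamine ABC transporter substrate binding, permease	with	27	2	74	1	1
LP_23680	MPNKWWRLILGVMLVLSWAIPVRA|AT	cell surface protein	with	24	2	79	0	1
LP_28170	MKKMMRWLGAILVMISGLSAVVPAQA|AN	cell surface protein	with	26	3	77	1	1
LP_23160	MQKRLRLSLGMLLAVVASLLMMGQVASA|DQ	hypothetical protein	with	28	3	71	1	1
LP_24320	MRFAGKLKKVMIALVAAVTFSTAGLGIAGADLQAQA|AS	D-alanyl-D-alanine carboxypeptidase	with	36	4	72	1	1
LP_14210	MKKIVNWLLGSVLMIAAVTMLSSVSANA|ST	hypothetical protein	with	28	2	68	1	1
LP_09710	MRRLLTGTLVVGGLLLVVCLMAVNGQA|KV	extracellular protein	with	27	2	74	0	1
PA_18600	MVKSRNRILHYILVAVSVVIVVLGFSVIKASA|HG	chitin-binding protein	with	32	3	66	1	1
PA_13510	MYKGFKKYFSNGADRKAGNYPVAKRNKRWLLASAVMLAMFGAGMAQSHAFA|KA	hypothetical protein	with	51	9	59	1	1
PA_18250	MKLKAKLLLVVVPFLMGSVVYHPTPTVQA|KT	DNA-entry nuclease	with	29	3	69	0	1
PA_08950	MNQNWQKPSPKLNWVRFYSIVTILVLVTSVAGLEMLRVSA|HQ	beta-lactamase class A	with	40	3	58	0	1
PA_17320	MKKARWKLLLAGLALLGGISLGQNIISA|NT	hypothetical protein	with	28	4	71	0	1
PA_10610	MKRKWFSLLVAVFLIIGVAIGFGGILHSKSSG|ND	hypothetical protein	with	32	3	72	0	1
PA_04150	MKKAITTASFFLAIFVVFMVGSNAASA|KS	hypothetical protein	with	27	2	70	1	1
PA_07000	METKKRFKMYKSGKKWLVAAIVAGGIATAGSVASVNA|DE	hypothetical protein	with	38	7	59	0	1
LP_27290	MRRKLVGYMLSMLTVILALFMLGSTAHA|KE	cell surface protein	without	28	3	68	1	1
LP_27220	MKKINKLMILGMLVLGVTGATMINPEMTTA|AH	extracellular protein	without	30	3	67	0	1
LP_17340	MKKRFGWFLAIIVALIMTVVPLGQTQHAQA|AD	ABC transporter substrate-binding and permease protein	without	30	3	70	1	1
LP_11950	MTKRMSFKFKWVALVATLIVGIGSWQVLAHA|DS	hypothetical protein	without	31	4	68	1	1
LP_12630	MLKLIKQRLVWGLVLTATVSGVLSCNVAAHA|TS	D-alanyl-D-alanine carboxypeptidase	without	31	3	65	1	1
LP_28330	MKLSKRGLFWLLGLVSFAILLLFSQPLGAQA|AT	cell surface protein	without	31	3	74	1	1
LP_27010	MRKLIKACGLMVISMLVGLGIVTSALA|AK	cell surface protein, CscB family	without	27	3	74	1	1
PA_14540	MKNNKIIITAAIAGLLGGGVAYGGASFVQNRMEA|TT	serine protease	without	34	2	68	0	1
PA_15330	MNYRSILFTTAIATMGAFSFGHSPVSA|HS	hydrolase	without	27	1	59	0	0
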