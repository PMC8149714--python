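# Genes of the recurrently deleted region of D. radiodurans chromosome II
# (wt-1999 coordinates, 1-based inclusive).  The published annotation table
# gives no strand; strand is stored as "+" as a placeholder and only the
# coordinates, products and COG class letters are meaningful here.
# cog "-" means no COG assignment.
gene_id	element	start	end	strand	product	cog
DR_A0181	chrII	186398	187486	+	GGDEF family protein	T
DR_A0182	chrII	187602	188408	+	Hypothetical protein	L
DR_A0183	chrII	188559	189953	+	Hypothetical protein	R
DR_A0184	chrII	190143	191132	+	Pyridoxamine kinase	H
DR_A0185	chrII	191098	192645	+	Exopolyphosphatase	FP
DR_A0186	chrII	192795	193784	+	Cytochrome P450, putative	Q
DR_A0188	chrII	194287	197055	+	Excinuclease ABC subunit A	L
DR_A0189	chrII	197036	198550	+	Ribosomal protein S12 methylthiotransferase	J
DR_A0190	chrII	198551	200122	+	Hypothetical protein	-
DR_A0191	chrII	200157	201089	+	Hypothetical protein	G
DR_A0192	chrII	201063	201476	+	Hypothetical protein	-
DR_A0193	chrII	201536	202249	+	Phosphoglycerate mutase-like protein	G
DR_A0194	chrII	202242	203402	+	Hypothetical protein	R
DR_A0195	chrII	203399	204235	+	Short chain dehydrogenase/reductase family oxidoreductase	IQR
DR_A0196	chrII	204324	205571	+	Acyl-CoA dehydrogenase	I
DR_A0197	chrII	205568	205975	+	Hypothetical protein	-
DR_A0198	chrII	205972	206466	+	Hypothetical protein	Q
DR_A0199	chrII	206499	206960	+	Nodulation protein N-like protein	I
DR_A0200	chrII	206957	207733	+	Gluconate 5-dehydrogenase	IQR
DR_A0201	chrII	207944	208807	+	NAD synthetase	H
DR_A0202	chrII	208882	210270	+	Cu/Zn family superoxide dismutase	P
DR_A0203	chrII	210267	211598	+	Oxidoreductase	G
DR_A0204	chrII	211623	212054	+	Response regulator	T
DR_A0205	chrII	212051	213649	+	Sensor histidine kinase	T
DR_A0206	chrII	213762	215597	+	Oligoendopeptidase F	E
DR_A0207	chrII	215676	217316	+	Hypothetical protein	S
DR_A0208	chrII	217422	218531	+	Peptide ABC transporter permease	EP
DR_A0209	chrII	218528	219514	+	Peptide ABC transporter permease	EP
DR_A0210	chrII	220213	221475	+	Peptide ABC transporter, periplasmic peptide-binding protein	E
DR_A0211	chrII	221435	222274	+	GntR family transcriptional regulator	K
DR_A0212	chrII	221476	223224	+	Hypothetical protein	O
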