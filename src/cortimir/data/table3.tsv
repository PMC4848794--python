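gene_id	gene_symbol	description	in_silico
11479	Acvr1b	activin A receptor, type 1B	False
12064	Bdnf	brain derived neurotrophic factor	True
108699	Chn1	chimerin 1	False
211922	Dennd6a	DENN/MADD domain containing 6A	False
14357	Dtx1	deltex 1 homolog (Drosophila)	False
433940	Fam222a	family with sequence similarity 222, member A	True
14782	Gsr	glutathione reductase	False
15245	Hhip	Hedgehog-interacting protein	False
15394	Hoxa1	homeobox A1	False
66383	Iscu	IscU iron-sulfur cluster scaffold homolog (E. coli)	True
74287	Kcmf1	potassium channel modulatory factor 1	True
216858	Kctd11	potassium channel tetramerisation domain containing 11	False
17992	Ndufa4	NADH dehydrogenase (ubiquinone) 1 alpha subcomplex, 4	True
320717	Pptc7	PTC7 protein phosphatase homolog (S. cerevisiae)	True
244058	Rgma	repulsive guidance molecule family member A	False
104001	Rtn1	reticulon 1	False
67956	Setd8	SET domain containing (lysine methyltransferase) 8	False
67582	Slc25a26	solute carrier family 25 (mitochondrial carrier, phosphate carrier), member 26	False
240057	Syngap1	synaptic Ras GTPase activating protein 1 homolog (rat)	True
21416	Tcf7l2	transcription factor 7 like 2, T cell specific, HMG box	False
210573	Tmem151b	transmembrane protein 151B	True
56338	Txnip	thioredoxin interacting protein	False
213742	Xist	inactive X specific transcripts	False
21769	Zfand3	zinc finger, AN1-type domain 3	False
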