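class	gene_id	gene_symbol	trust	targetscan_span	novel	in_wang	in_he
1	72168	Aifm3	Present	Mouse and Human	True	False	False
1	12043	Bcl2	Present	Mouse and Human	False	True	False
1	18033	Nfkb1	Present	Mouse and Human	True	False	False
1	12176	Bnip3	Present	Mouse and Human	True	False	False
1	20423	Shh	Present	Mouse and Human	True	False	False
1	20852	Stat6	Present	Mouse and Human	True	False	False
1	21416	Tcf7l2	Present	Mouse and Human	True	False	False
2	56336	B4galt5	Probably present	Mouse and Human	False	True	False
2	66383	Iscu	Probably present	Mouse and Human	False	True	False
2	12064	Bdnf	Probably present	Mouse and Human	False	True	False
2	53417	Hif3a	Probably present	Mouse and Human	False	True	False
2	13638	Efna3	Probably present	Mouse and Human	True	False	False
2	17992	Ndufa4	Probably present	Mouse and Human	False	True	False
3	333433	Gpd1l	Not likely present	Mouse and Human	False	True	True
3	381022	Kmt2d	Not likely present	Mouse and Human	False	True	False
3	22661	Zfp148	Not likely present	Mouse and Human	True	False	False
3	68041	Mid1ip1	Not likely present	Mouse and Human	False	True	False
3	231207	Cpeb2	Not likely present	Mouse and Human	True	False	False
3	170729	Scrt1	Not likely present	Mouse and Human	True	False	False
3	240057	Syngap1	Not likely present	Mouse and Human	False	False	True
3	74287	Kcmf1	Not likely present	Mouse and Human	False	True	False
3	18013	Neurod2	Not likely present	Mouse and Human	True	False	False
4	207393	Elfn2	Absent	Mouse and Human	False	True	False
4	17258	Mef2a	Absent	Mouse and Human	True	False	False
4	74244	Atg7	Absent	Mouse and Human	False	True	False
5	69662	2310061I04Rik	Absent	Mouse or Human	False	True	False
5	225791	Zadh2	Absent	Mouse or Human	False	True	False
5	52132	Ccdc97	Absent	Mouse or Human	False	True	False
5	210573	Tmem151b	Absent	Mouse or Human	True	False	False
5	20362	Sept8	Absent	Mouse or Human	True	False	False
5	433940	Fam222a	Absent	Mouse or Human	True	False	False
5	320717	Pptc7	Absent	Mouse or Human	False	True	False
5	545554	Ankrd34a	Absent	Mouse or Human	True	False	False
5	11515	Adcy9	Absent	Mouse or Human	True	False	False
5	102247	Agpat6	Absent	Mouse or Human	True	False	False
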