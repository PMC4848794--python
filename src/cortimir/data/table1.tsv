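mature_mirna	mean_count_33c	mean_rpm_33c	mean_count_39c	mean_rpm_39c	log2_ratio	fdr
mmu-miR-92a-1-5p	13060	11962.26	1109	960.10	-3.64	7.81e-90
mmu-miR-155-3p	891	812.58	87	75.06	-3.44	3.67e-59
mmu-miR-147-3p	5616	5189.40	1393	1241.44	-2.06	6.53e-34
mmu-miR-152-5p	3649	3319.82	900	761.91	-2.12	2.93e-33
mmu-miR-210-5p	2652	2437.48	654	572.17	-2.09	4.41e-32
mmu-miR-222-5p	1469	1346.34	368	326.79	-2.04	1.69e-29
mmu-miR-148a-5p	372	343.95	87	75.31	-2.19	6.69e-23
mmu-miR-147-5p	75	71.04	4	3.83	-4.21	1.66e-17
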