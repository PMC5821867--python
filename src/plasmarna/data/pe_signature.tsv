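transcript	transcript_id	biotype	mean_counts	fold_change	p_value	adjusted_p_value
mitochondrially encoded tRNA proline	ENST00000387461	Mitochondrial tRNA	490	4.25	1.65e-16	1.57e-14
mitochondrially encoded tRNA lysine	ENST00000387421	Mitochondrial tRNA	433	2.27	3.43e-06	1.63e-04
microRNA 182	ENST00000385255	miRNA	1325	0.54	5.45e-06	1.73e-04
microRNA 10b	ENST00000385011	miRNA	7115	0.50	8.96e-06	2.13e-04
mucin 2, oligomeric mucus/gel-forming	ENST00000361558	processed transcript	901	2.34	1.68e-05	3.19e-04
microRNA 25	ENST00000384816	miRNA	5585	0.61	5.38e-05	6.39e-04
RP11-259O2.3-001	ENST00000514519	lincRNA	409	2.97	4.92e-05	6.39e-04
microRNA 4433b	ENST00000581329	miRNA	473	1.71	4.98e-05	6.39e-04
mitochondrially encoded tRNA histidine	ENST00000387441	Mitochondrial tRNA	247	1.95	9.21e-05	9.72e-04
HELLP associated long non-coding RNA	ENST00000626826	macro lncRNA	729	2.02	1.08e-04	1.03e-03
microRNA 99b	ENST00000384819	miRNA	344	0.65	1.57e-04	1.31e-03
microRNA 143	ENST00000385300	miRNA	1632	0.62	1.66e-04	1.31e-03
mitochondrially encoded tRNA valine	ENST00000387342	Mitochondrial tRNA	664	1.99	2.11e-04	1.54e-03
microRNA 151a	ENST00000521276	miRNA	10021	0.75	5.68e-04	3.85e-03
microRNA 191	ENST00000384873	miRNA	31187	0.75	6.26e-04	3.97e-03
RNA, 5.8S ribosomal pseudogene 4	ENST00000365096	rRNA	1652	1.68	1.65e-03	9.21e-03
mitochondrially encoded tRNA serine 2 (AGU/C)	ENST00000387449	Mitochondrial tRNA	1250	1.72	1.61e-03	9.21e-03
microRNA 146b	ENST00000365699	miRNA	1323	0.75	2.67e-03	1.41e-02
microRNA 221	ENST00000385135	miRNA	587	1.44	3.97e-03	1.98e-02
mitochondrially encoded tRNA tyrosine	ENST00000387409	Mitochondrial tRNA	173	1.53	4.41e-03	2.09e-02
mitochondrially encoded 16S RNA	ENST00000387347	Mitochondrial tRNA	6218	1.63	4.82e-03	2.18e-02
microRNA let-7g	ENST00000362280	miRNA	1073	1.27	9.85e-03	4.26e-02
long intergenic non-protein coding RNA 324	ENST00000315707	lincRNA	1087	1.50	1.03e-02	4.27e-02
AC113133.1-201 (microRNA-486)	ENST00000612171	miRNA	17569	0.70	1.11e-02	4.38e-02
AC020956.3-001	ENST00000614316	lincRNA	902	1.71	1.18e-02	4.47e-02
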