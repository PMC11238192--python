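name	printed_category	notation	length	dna_gap	gc_percent	tm_c	off_target	dg_mut_kcal	dg_wt_kcal
2'-OMe-1	gapmer	[CCACGC] T∗C∗A∗C∗C∗C∗T∗T∗T∗G∗ [GCCCGA]	22	10	68.2	75.2	no	−34.24	−16.62
2'-OMe-2	gapmer	[CCACGCU] C∗A∗C∗C∗C∗T∗T∗T∗ [GGCCCGA]	22	8	68.2	76.5	no	−34.24	−16.62
2'-OMe-3	gapmer	[ACCACG] C∗T∗C∗A∗C∗C∗C∗T∗T∗T∗ [GGCCCG]	22	10	68.2	76.8	no	−34.29	−14.66
2'-OMe-4	gapmer	[ACCACGC] T∗C∗A∗C∗C∗C∗T∗T∗ [UGGCCCG]	22	8	68.2	77.5	no	−34.29	−14.66
2'-OMe-5	gapmer	[ACCACG] C∗T∗C∗A∗C∗C∗C∗T∗ [UUGGCC]	20	8	65	74.2	no	−29.54	−11.44
2'-OMe-6	gapmer	[CACGCU] C∗A∗C∗C∗C∗T∗T∗T∗ [GGCCCG]	20	8	70	72.7	no	−31.34	−14.73
2'-OMe-7	gapmer	[CCACG] C∗T∗C∗A∗C∗C∗C∗T∗ [UUGGC]	18	8	66.7	69.3	yes	−26.58	−11.59
2'-OMe-8	gapmer	[ACGCU] C∗A∗C∗C∗C∗T∗T∗T∗ [GGCCC]	18	8	66.7	70.8	yes	−27.84	−13.54
2'-OMe-9	gapmer	[ACG] C∗T∗C∗A∗C∗C∗C∗T∗ [UUG]	14	8	57.1	55.2	yes	−20.07	−11.43
2'-MOE-1	gapmer	<CCACGCT> C∗A∗C∗C∗C∗T∗T∗T∗ <GGCCCGA>	22	8	68.2	64.5	no	−34.24	−16.62
2'-MOE-2	gapmer	<ACCACG> C∗T∗C∗A∗C∗C∗C∗T∗T∗T∗ <GGCCCG>	23	11	65.2	66	no	−34.89	−14.66
2'-MOE-3	gapmer	<CACG> C∗T∗C∗A∗C∗C∗C∗T∗T∗T∗ <GGCC>	18	9	66.7	57.8	yes	−26.59	−10.06
LNA-1	gapmer	{CGC} T∗C∗A∗C∗C∗C∗T∗ {TTG}	13	7	61.5	58.2	yes	−18.45	−11.43
LNA-2	gapmer	{CAC} G∗C∗ {T} C∗A∗C∗C∗C∗T∗T∗T∗ {G} G∗C∗ {CCG}	19	8	70	75.6	no	−27.48	−11.42
LNA-3	gapmer	{ACG} C∗T∗C∗A∗C∗C∗C∗T∗T∗T∗ {GGC}	16	10	62.5	63.9	yes	−22.05	−10.56
M-1	mixmer	[CCA] C∗G∗C∗ [UCA] C∗C∗C∗ [UUU] G∗G∗C∗ [CCG]	21	3	71.4	56.1	no	−33.71	−14.70
M-2	mixmer	[GGC] G∗G∗A∗ [CCA] C∗G∗C∗ [UCA] C∗C∗C∗ [UUU]	21	3	66.7	58.8	no	−30.37	−21.36
M-3	mixmer	[CA] C∗G∗C∗ [UCA] C∗C∗C∗ [UUU] G∗G∗C∗ [CC]	19	3	68.4	53.4	yes	−30.15	−13.54
M-4	mixmer	[CCA] C∗G∗C∗ [UCA] C∗C∗C∗ {UUU}	15	3	60	52.2	yes	−22.41	−11.86
M-5	mixmer	[CCAC] G∗C∗T∗ [CACCCU] T∗T∗G∗ [GCCC]	20	3	70	63.4	yes	−32.52	−13.51
M-6	mixmer	[CUC] A∗C∗C∗ [CUUU] G∗G∗C∗ [CCG]	16	3	68.8	44.3	yes	−23.42	−15.87
M-7	mixmer	[GAC] C∗A∗C∗G∗ [CUC] A∗C∗C∗ [CUUU] G∗G∗C∗ [CCG]	23	4	69.6	60	no	−37.82	−16.17
MM(1-7)	mismatch_mixmer	[GAC] C∗A∗C∗G∗ [CUC] A∗C∗C∗ [CUAU] G∗G∗C∗ [CCG]	23	4	69.6	63.6	no	−31.49	−15.35
MM(2-7)	mismatch_mixmer	[GAC] C∗A∗C∗G∗ [CUC] A∗C∗C∗ [CUUA] G∗G∗C∗ [CCG]	23	4	69.6	61.8	no	−31.09	−18.14
MM(3-7)	mismatch_mixmer	[GAC] C∗A∗C∗G∗ [CUC] A∗C∗C∗ [CUUU] C∗G∗C∗ [CCG]	23	4	69.6	60	no	−29.88	−21.09
MM(4-7)	mismatch_mixmer	[GAC] C∗A∗C∗G∗ [CUC] A∗C∗C∗ [CUUU] G∗C∗C∗ [CCG]	23	4	69.6	60.5	no	−29.06	−17.72
MM(5-7)	mismatch_mixmer	[GAC] C∗A∗C∗G∗ [CUC] A∗C∗C∗ [CUUU] G∗G∗G∗ [CCG]	23	4	69.6	60.5	no	−27.46	−12.8
MM(6-7)	mismatch_mixmer	[GAC] C∗A∗C∗G∗ [CUC] A∗C∗C∗ [CUUU] G∗G∗C∗ [GCG]	23	4	69.6	60.5	no	−28.32	−12.59
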