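# 2D-DIGE spots differentially expressed along the wild-type crypt-villus axis.
# Comparison: WT villus (first) vs WT crypt (second); DeCyder signed average
# fold change, magnitude >= 1, negative = higher in the second condition.
spot_id	accession	gene	protein_name	mw_kda	pi	avg_fold_change	overall_trend	comparison_first	comparison_second
1320	Q3TEN9	Gyk	Glycerol kinase	57.4	5.76	-2.58	Up	WTV	WTC
1400	NP_032974	Psmc3	26S protease regulatory subunit 6A	44.6	5.02	-2.84	Up	WTV	WTC
1800	B2CY77	Rpsa	Laminin receptor	32.8	4.87	2.58	Down	WTV	WTC
1952	P14869	Rplp0	60S acidic ribosomal protein P0	34.2	6.25	-2.96	Up	WTV	WTC
1961	Q61264	Acta1	Skeletal muscle alpha-actin mRNA	37.7	5.54	2.94	Down	WTV	WTC
2541	P35282	Rab21	Ras-related protein Rab-21	24.1	7.94	2.24	Down	WTV	WTC
2992	A0A087WQ08	Fam135a	Family with sequence similarity 135	30.5	7.01	2.89	Down	WTV	WTC
3086	Q9Z1R9	Prss1	protease, serine 1 (trypsin 1)	26.1	4.94	12.35	Down	WTV	WTC
3247	Q9D1A2	Cndp2	Cytosolic non-specific dipeptidase	52.7	5.66	-2.51	Up	WTV	WTC
3254	E9Q223	Hbb-bs	Protein Hbb-bs	11.1	6.37	18.52	Down	WTV	WTC
3261	P51162	Fabp6	Gastrotropin	14.5	6.15	-4.23	Up	WTV	WTC
3268	P17918	Pcna	Proliferating cell nuclear antigen	28.8	4.77	-2.21	Up	WTV	WTC
3281	P12710	Fabp1	Fatty acid-binding protein	14.2	8.56	4.01	Down	WTV	WTC
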