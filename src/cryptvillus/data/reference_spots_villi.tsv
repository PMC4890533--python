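# 2D-DIGE spots differentially expressed between villi of the two genotypes.
# Comparison: WT villus (first) vs PepT1 KO villus (second).
spot_id	accession	gene	protein_name	mw_kda	pi	avg_fold_change	overall_trend	comparison_first	comparison_second
1372	P56480	Atp5b	ATP synthase subunit beta, mitochondrial	56.3	5.34	-2.28	Up	WTV	KOV
1400	NP_032974	Psmc3	26S protease regulatory subunit 6A	44.6	5.02	-2.31	Up	WTV	KOV
1789	Q9D154	Serpinb1a	Leukocyte elastase inhibitor A	42.5	6.21	3.94	Down	WTV	KOV
1794	Q3TJ66	Aldob	Fructose-bisphosphate aldolase	39.5	8.27	2.84	Down	WTV	KOV
1870	Q3UAS2	Capza1	capping protein (actin filament) muscle Z-line, alpha 1	32.9	5.55	-2.32	Up	WTV	KOV
1875	Q3U804	Actb	Actin, Beta	41.8	6.30	-2.22	Up	WTV	KOV
2537	P10649	Gstm1	Glutathione S-transferase Mu 1	26.0	7.94	2.09	Down	WTV	KOV
2541	P35282	Rab21	Ras-related protein Rab-21	24.1	7.94	4.58	Down	WTV	KOV
2992	A0A087WQ08	Fam135a	Family with sequence similarity 135	30.5	7.01	2.4	Down	WTV	KOV
3254	E9Q223	Hbb-bs	Protein Hbb-bs	11.1	6.37	2.29	Down	WTV	KOV
3257	Q9Z1R9	Prss1	protease, serine 1 (trypsin 1)	26.1	4.94	2.14	Down	WTV	KOV
3281	P12710	Fabp1	Fatty acid-binding protein	14.2	8.56	2.16	Down	WTV	KOV
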