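# 2D-DIGE spots differentially expressed along the PepT1-knockout crypt-villus
# axis.  Comparison: KO villus (first) vs KO crypt (second).
spot_id	accession	gene	protein_name	mw_kda	pi	avg_fold_change	overall_trend	comparison_first	comparison_second
1118	P50544	Acadvl	Very long-chain specific acyl-CoA dehydrogenase, mitochondrial	70.8	8.75	2.61	Down	KOV	KOC
1266	P68373	Tuba1c	Tubulin alpha-1C chain	49.9	5.10	-2.15	Up	KOV	KOC
1320	Q3TEN9	Gyk	Glycerol kinase	57.4	5.76	-2.64	Up	KOV	KOC
1496	Q8VH52	Eif4a1	Eukaryotic translation initiation factor 4A1	16.1	5.15	2.78	Down	KOV	KOC
1732	Q9D154	Serpinb1a	Leukocyte elastase inhibitor A	42.5	6.21	-3.20	Up	KOV	KOC
1794	Q3TJ66	Aldob	Fructose-bisphosphate aldolase	39.5	8.27	-2.06	Up	KOV	KOC
1800	B2CY77	Rpsa	Laminin receptor	32.8	4.87	4.23	Down	KOV	KOC
1952	P14869	Rplp0	60S acidic ribosomal protein P0	34.2	6.25	-3.78	Up	KOV	KOC
2346	Q9Z1R9	Prss1	protease, serine 1 (trypsin 1)	26.1	4.94	4.23	Down	KOV	KOC
2529	Q3U0B3	Dhrs11	Dehydrogenase	28.3	6.34	-3.33	Up	KOV	KOC
3254	E9Q223	Hbb-bs	Protein Hbb-bs	11.1	6.37	18.87	Down	KOV	KOC
3261	P51162	Fabp6	Gastrotropin	14.5	6.15	-6.16	Up	KOV	KOC
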