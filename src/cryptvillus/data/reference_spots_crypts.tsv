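# 2D-DIGE spots differentially expressed between crypts of the two genotypes.
# Comparison: WT crypt (first) vs PepT1 KO crypt (second).
spot_id	accession	gene	protein_name	mw_kda	pi	avg_fold_change	overall_trend	comparison_first	comparison_second
1875	Q3U804	Actb	Actin, Beta	41.8	6.30	-3.16	Up	WTC	KOC
2537	P10649	Gstm1	Glutathione S-transferase Mu 1	26.0	7.94	2.03	Down	WTC	KOC
3235	P51162	Fabp6	Gastrotropin	14.5	6.15	2.27	Down	WTC	KOC
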