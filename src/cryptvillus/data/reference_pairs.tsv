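# The four published miRNA-protein pairs with their four-group relative
# expression levels (WTV, WTC, KOV, KOC).  Protein levels for Gyk,
# Serpinb1a and Rpsa are DIGE-derived and normalized within genotype, so
# only the two axis comparisons are scale-comparable for them; Actb levels
# share one cross-genotype scale.  miRNA panel levels share one scale.
spot_id	protein_name	gene	p_WTV	p_WTC	p_KOV	p_KOC	protein_comparable	mirna	m_WTV	m_WTC	m_KOV	m_KOC	mirna_comparable
1320	Glycerol kinase	Gyk	1	2.58	1	2.64	wt_axis,ko_axis	miR-33-5p	1	0.20	1.76	0.34	wt_axis,ko_axis,villi,crypts
1789	Leukocyte elastase inhibitor A	Serpinb1a	1	0.85	0.25	0.85	wt_axis,ko_axis	miR-221-3p	1	1.22	1.64	1.11	wt_axis,ko_axis,villi,crypts
1800	Laminin receptor	Rpsa	2.58	1	4.23	1	wt_axis,ko_axis	miR-200c-5p	1	2.20	0.80	1.05	wt_axis,ko_axis,villi,crypts
1875	Actin, beta	Actb	1	1	2.22	3.16	wt_axis,ko_axis,villi,crypts	miR-212-3p	1	1.06	0.67	0.61	wt_axis,ko_axis,villi,crypts
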