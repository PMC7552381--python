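feature_id	log2fc	pvalue	fdr	contrast
mmu-miR-582-3p	-3.02	0.00051	0.0455	EAE10-vs-BL
mmu-miR-582-3p	-3.034	8.36E-05	0.0191	Mock10-vs-BL
mmu-miR-7654-3p	4.91	1.67E-05	0.0057	EAE20-vs-EAE10
mmu-miR-146a-5p	3.139	5.28E-05	0.0074	EAE20-vs-EAE10
mmu-miR-466i-3p	3.44	7.09E-05	0.0074	EAE20-vs-EAE10
mmu-miR-6944-5p	4.445	0.0001	0.0074	EAE20-vs-EAE10
mmu-miR-342-3p	3.685	0.00013	0.0077	EAE20-vs-EAE10
mmu-miR-155-5p	2.955	0.00028	0.0122	EAE20-vs-EAE10
mmu-miR-1193-5p	3.857	0.00032	0.0122	EAE20-vs-EAE10
mmu-miR-221-3p	2.31	0.00054	0.0168	EAE20-vs-EAE10
mmu-miR-203-3p	2.268	0.00063	0.0182	EAE20-vs-EAE10
mmu-miR-1249-3p	2.603	0.00082	0.0217	EAE20-vs-EAE10
mmu-miR-210-3p	2.569	0.00092	0.0225	EAE20-vs-EAE10
mmu-miR-28a-3p	2.405	0.00099	0.0225	EAE20-vs-EAE10
mmu-miR-667-3p	2.598	0.00165	0.0354	EAE20-vs-EAE10
mmu-miR-3093-5p	2.625	0.00236	0.0449	EAE20-vs-EAE10
mmu-miR-8114	2.343	0.00236	0.0449	EAE20-vs-EAE10
mmu-miR-6983-5p	-4.023	9.10E-05	0.0074	EAE20-vs-EAE10
mmu-miR-219c-3p	-3.701	0.00051	0.0168	EAE20-vs-EAE10
mmu-miR-190a-5p	-2.563	0.00029	0.0122	EAE20-vs-EAE10
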