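feature_id	log2fc	pvalue	fdr	contrast
mmu-miR-142a-5p	6.426	1.65E-05	0.0022	EAE20-vs-Mock20
mmu-miR-146a-5p	3.278	0.00016	0.0076	EAE20-vs-Mock20
mmu-miR-10b-5p	-3.015	0.00016	0.0076	EAE20-vs-Mock20
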