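cohort_id	group	n_total	n_hap_possible	phenotype_desc
southampton	MISSING_HERITABILITY	51	49	Nystagmus and/or albinism (England)
hutton_spritz_2008a	MISSING_HERITABILITY	20	1	AROA / mild OCA (USA, Canada, N. Europe)
hutton_spritz_2008b	MISSING_HERITABILITY	13	3	OCA (USA, Canada, N. Europe)
oetting_2009	MISSING_HERITABILITY	3	2	OCA1
ghodsinejad_2022	MISSING_HERITABILITY	6	0	OCA1 (Iranian)
lasseaux_2018	MISSING_HERITABILITY	158	64	Nystagmus and/or absence of fovea (France)
gronskov_2019	MISSING_HERITABILITY	29	21	Albinism: OCA, AROA or OA (Scandinavian)
campbell_2019	MISSING_HERITABILITY	4	4	Nystagmus plus ocular albinism feature, no skin hypopigmentation (England)
hutton_spritz_2008b	MOLECULARLY_DIAGNOSED	71	2	OCA (USA, Canada, N. Europe)
oetting_2009	MOLECULARLY_DIAGNOSED	9	0	OCA1
ghodsinejad_2022	MOLECULARLY_DIAGNOSED	19	0	OCA1 (Iranian)
gronskov_2019	MOLECULARLY_DIAGNOSED	2	0	Albinism: OCA, AROA or OA (Scandinavian)
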