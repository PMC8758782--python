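cohort_id	group	n_total	n_hap_possible	n_informative	n_cis_in_trans	phenotype_desc
southampton	MISSING_HERITABILITY	51	49	23	23	Nystagmus and/or albinism (England)
oetting_2009	MISSING_HERITABILITY	3	2	2	2	OCA1
ghodsinejad_2022	MISSING_HERITABILITY	6	0	0	0	OCA1 (Iranian)
lasseaux_2018	MISSING_HERITABILITY	158	64	31	31	Nystagmus and/or absence of fovea (France)
gronskov_2019	MISSING_HERITABILITY	29	21	6	6	Albinism: OCA, AROA or OA (Scandinavian)
campbell_2019	MISSING_HERITABILITY	4	4	2	2	Nystagmus plus ocular albinism feature, no skin hypopigmentation (England)
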