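term	obs	odds_ratio	p_value	corr_p_value
keratin filament	6	102,352	3,62292E-10	1,19194E-07
pattern specification process	6	12,3435	2,01548E-05	0,00331547
regionalization	5	14,3981	0,000048482	0,00531685
cranial nerve morphogenesis	2	116,248	0,000331888	0,0272978
kidney development	3	21,403	0,000559756	0,0306933
zinc ion binding	16	2,99882	0,000514454	0,0338511
embryonic development	6	5,58735	0,00120012	0,0564059
receptor signaling protein serine/threonine kinase activity	4	8,11769	0,00208634	0,0624006
developmental process	20	2,38882	0,00204634	0,0673246
negative regulation of MAP kinase activity	2	19,4953	0,00596027	0,0676182
regulation of transcription factor import into nucleus	2	31,8952	0,00251195	0,0688694
cation binding	19	2,14904	0,00649842	0,071266
anterior/posterior pattern formation	3	13,3725	0,00198155	0,0724365
cytoskeletal part	8	3,92527	0,00191605	0,0787977
inner ear morphogenesis	2	27,0115	0,00335617	0,0788701
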