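scenario	family	species_a	species_b	cluster	n_a	n_b
sorghum_maize_ALDH2	2	sorghum	maize	1	1	2
sorghum_maize_ALDH2	2	sorghum	maize	2	1	1
sorghum_maize_ALDH2	2	sorghum	maize	3	1	1
sorghum_maize_ALDH2	2	sorghum	maize	4	1	1
sorghum_maize_ALDH2	2	sorghum	maize	5	1	1
sorghum_maize_ALDH3	3	sorghum	maize	1	1	2
sorghum_maize_ALDH3	3	sorghum	maize	2	1	1
sorghum_maize_ALDH3	3	sorghum	maize	3	1	1
sorghum_maize_ALDH3	3	sorghum	maize	4	1	1
sorghum_maize_ALDH5	5	sorghum	maize	1	1	1
sorghum_maize_ALDH5	5	sorghum	maize	2	0	1
sorghum_maize_ALDH10	10	sorghum	maize	1	1	1
sorghum_maize_ALDH10	10	sorghum	maize	2	1	1
sorghum_maize_ALDH10	10	sorghum	maize	3	0	1
sorghum_maize_ALDH18	18	sorghum	maize	1	1	1
sorghum_maize_ALDH18	18	sorghum	maize	2	1	1
sorghum_rice_ALDH3	3	sorghum	rice	1	1	1
sorghum_rice_ALDH3	3	sorghum	rice	2	1	1
sorghum_rice_ALDH3	3	sorghum	rice	3	1	1
sorghum_rice_ALDH3	3	sorghum	rice	4	1	1
sorghum_rice_ALDH3	3	sorghum	rice	5	0	1
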