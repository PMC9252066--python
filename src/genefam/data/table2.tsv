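sl_no	locus_1	locus_2	ka	ks	ka_ks	time_mya	dup_type
1	SbALDH2B1	SbALDH2B2	0	0	inf	Not determinable	Segmental
2	SbALDH2C1	SbALDH2C2	0.1664	2.5295	0.0657	84.31	Tandem
3	SbALDH3E1	SbALDH3E2	0.228	0.7719	0.2953	25.73	Segmental
4	SbALDH3H1	SbALDH3H2	0.2294	1.5649	0.1465	52.16	Segmental
5	SbALDH10A1	SbALDH10A2	0.1584	1.0913	0.1451	36.37	Segmental
6	SbALDH18B1	SbALDH18B2	0.1399	1.0607	0.1318	35.35	Segmental
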