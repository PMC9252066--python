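family	locus_id	transcript_id	name	start	end	transcript_nt	cds_nt	protein_aa	domain_start	domain_end	ps00687	ps00070	mw_kda	pi	localization
2	Sobic.004G250900	Sobic.004G250900.2	SbALDH2B1a	59721748	59725595	2967	1272	423	1	413	Yes	Yes	45.67	6.38	Mitochondrion
2	Sobic.004G250900	Sobic.004G250900.3	SbALDH2B1b	59720135	59725595	3507	1656	551	79	541	Yes	Yes	58.79	6.65	Mitochondrion
2	Sobic.004G250900	Sobic.004G250900.4	SbALDH2B1c	59720879	59725595	3246	1656	551	79	541	Yes	Yes	58.79	6.65	Mitochondrion
2	Sobic.010G113000	Sobic.010G113000.1	SbALDH2B2a	11756541	11766808	2429	1671	556	84	546	Yes	Yes	60.09	7.20	Mitochondrion
2	Sobic.010G113000	Sobic.010G113000.2	SbALDH2B2b	11759710	11766808	2630	1644	547	75	537	Yes	Yes	59.21	6.65	Mitochondrion
2	Sobic.003G203500	Sobic.003G203500.1	SbALDH2C1a	53331225	53339384	1971	1506	501	29	491	Yes	Yes	54.33	5.99	Chloroplast
2	Sobic.003G203500	Sobic.003G203500.2	SbALDH2C1b	53331225	53339384	2060	1272	423	29	416	Yes	Yes	45.73	5.84	Chloroplast
2	Sobic.003G203600	Sobic.003G203600.1	SbALDH2C2a	53368965	53376601	2043	1515	504	32	494	Yes	Yes	54.24	5.47	Chloroplast
2	Sobic.003G203600	Sobic.003G203600.2	SbALDH2C2b	53368965	53376625	2264	1272	423	1	413	Yes	Yes	45.70	5.34	Chloroplast
2	Sobic.003G203600	Sobic.003G203600.3	SbALDH2C2c	53374514	53376601	1570	1245	414	1	404	Yes	Yes	44.65	5.23	Chloroplast
2	Sobic.010G178300	Sobic.010G178300.1	SbALDH2C3	51625698	51631645	2164	1566	521	45	511	Yes	Yes	56.26	5.78	Chloroplast
3	Sobic.004G300800	Sobic.004G300800.1	SbALDH3E1	63955597	63960188	1971	1461	486	1	442	Yes	Yes	54.19	6.59	Chloroplast
3	Sobic.006G163300	Sobic.006G163300.2	SbALDH3E2a	52091479	52098020	2119	1491	496	24	452	Yes	Yes	54.56	8.64	Chloroplast
3	Sobic.006G163300	Sobic.006G163300.3	SbALDH3E2b	52091484	52097728	1741	1491	496	24	452	Yes	Yes	54.56	8.64	Chloroplast
3	Sobic.005G064800	Sobic.005G064800.1	SbALDH3H1	7268869	7273754	2377	1437	478	1	431	Yes	Yes	52.05	8.07	Chloroplast
3	Sobic.008G057500	Sobic.008G057500.1	SbALDH3H2	5994822	6001133	1889	1464	487	1	437	Yes	Yes	52.42	9.45	Chloroplast
5	Sobic.004G058600	Sobic.004G058600.1	SbALDH5F1a	4685051	4695810	2412	1584	527	62	521	Yes	Yes	56.01	8.31	Mitochondrion
5	Sobic.004G058600	Sobic.004G058600.2	SbALDH5F1b	4685097	4695810	2075	1551	516	62	494	Yes	Yes	54.92	8.25	Mitochondrion
5	Sobic.004G058600	Sobic.004G058600.3	SbALDH5F1c	4685092	4695810	2261	1482	493	28	487	Yes	Yes	52.40	6.22	Mitochondrion
5	Sobic.004G058600	Sobic.004G058600.4	SbALDH5F1d	4687581	4695576	1953	1176	391	1	385	Yes	Yes	41.50	5.70	Mitochondrion
5	Sobic.004G058600	Sobic.004G058600.5	SbALDH5F1e	4685097	4695810	2108	1584	527	62	521	Yes	Yes	56.01	8.31	Mitochondrion
6	Sobic.002G062500	Sobic.002G062500.1	SbALDH6B1	6035846	6043359	2684	1623	540	55	519	No	Yes	57.84	5.89	Mitochondrion
7	Sobic.002G215700	Sobic.002G215700.1	SbALDH7B1	60779264	60786533	2031	1530	509	30	492	Yes	Yes	54.40	6.06	Mitochondrion
10	Sobic.006G109500	Sobic.006G109500.1	SbALDH10A1	47850314	47855384	2070	1521	506	18	488	Yes	Yes	55.06	5.94	Chloroplast, Mitochondrion, Peroxisome
10	Sobic.007G130800	Sobic.007G130800.1	SbALDH10A2a	54746028	54751628	1731	1518	505	18	487	Yes	Yes	54.91	5.16
10	Sobic.007G130800	Sobic.007G130800.2	SbALDH10A2b	54745913	54751628	1976	1182	393	1	375	Yes	Yes	42.75	4.85
11	Sobic.007G140700	Sobic.007G140700.1	SbALDH11A1	56977075	56981706	2088	1497	498	26	486	Yes	Yes	53.28	6.80	Cytoplasm
12	Sobic.009G212600	Sobic.009G212600.1	SbALDH12A1	55816131	55822788	2152	1650	549	55	510	Yes	Yes	60.58	6.90	Mitochondrion
18	Sobic.003G356000	Sobic.003G356000.1	SbALDH18B1	67427644	67434548	2783	2190	729	295	584	No	Yes	78.36	5.99	Cytoplasm
18	Sobic.009G160100	Sobic.009G160100.1	SbALDH18B2a	51779954	51800133	2804	2151	716	288	570	No	Yes	77.71	5.92	Cytoplasm
18	Sobic.009G160100	Sobic.009G160100.2	SbALDH18B2b	51779954	51800133	2800	2151	716	288	570	No	Yes	77.71	5.92	Cytoplasm
18	Sobic.009G160100	Sobic.009G160100.3	SbALDH18B2c	51779375	51787129	3460	2151	716	288	570	No	Yes	77.71	5.92	Cytoplasm
18	Sobic.009G160100	Sobic.009G160100.4	SbALDH18B2d	51779375	51787112	3447	2151	716	288	570	No	Yes	77.71	5.92	Cytoplasm
22	Sobic.002G426100	Sobic.002G426100.1	SbALDH22A1	77251658	77257367	2414	1782	593	52	521	Yes	Yes	65.45	7.48	Chloroplast
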