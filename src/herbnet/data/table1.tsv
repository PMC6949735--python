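ingredient_id	name	canonical_name	ob	dl	hl	degree	herb
mol01	Quercetin	quercetin	46.43	0.28	14.40	73	Coptis chinensis;Astragalus membranaceus
mol02	Ferulic acid	ferulic acid	39.56	0.06	2.38	7	Coptis chinensis
mol03	Palmatine	palmatine	64.60	0.65	2.25	9	Coptis chinensis
mol04	Jatrorrizine	jatrorrhizine	19.65	0.59	4.21	9	Coptis chinensis
mol05	Berberine	berberine	36.86	0.78	6.57	8	Coptis chinensis
mol06	Columbamine	columbamine	26.94	0.59	5.21	9	Coptis chinensis
mol07	Coptisine	coptisine	30.67	0.86	9.33	8	Coptis chinensis
mol08	Worenine	worenine	45.83	0.87	8.41	6	Coptis chinensis
mol09	Magnoflorine	magnoflorine	0.48	0.55	6.22	8	Coptis chinensis
mol10	Berberrubine	berberrubine	35.74	0.73	6.46	8	Coptis chinensis
mol11	Epiberberine	epiberberine	43.09	0.78	6.10	7	Coptis chinensis
mol12	(R)-Canadine	(r)-canadine	55.37	0.77	6.41	9	Coptis chinensis
mol13	Berlambine	berlambine	36.68	0.82	7.33	9	Coptis chinensis
mol14	Corchoroside A_qt	corchoroside a_qt	104.95	0.78	6.68	2	Coptis chinensis
mol15	Tetrandrine	tetrandrine	26.64	0.10	4.77	9	Coptis chinensis
mol16	β-Sitosterol	beta-sitosterol	36.91	0.75	5.36	15	Panax ginseng;Pulsatilla chinensis
mol17	Kaempferol	kaempferol	41.88	0.24	14.74	26	Panax ginseng
mol18	Stigmasterol	stigmasterol	43.83	0.76	5.57	10	Panax ginseng;Pulsatilla chinensis
mol19	β-Elemene	beta-elemene	25.63	0.06	6.32	8	Panax ginseng
mol20	Ginsenoside Ro_qt	ginsenoside ro_qt	17.62	0.76	7.50	1	Panax ginseng
mol21	Dianthramine	dianthramine	40.45	0.20	5.14	3	Panax ginseng
mol22	Arachidonate	arachidonate	45.57	0.20	7.56	5	Panax ginseng
mol23	Ginsenoside La_qt	ginsenoside la_qt	15.70	0.78	5.20	1	Panax ginseng
mol24	Ginsenoside rh2	ginsenoside rh2	36.32	0.56	11.08	9	Panax ginseng
mol25	Ginsenoside-Rh3_qt	ginsenoside rh3_qt	13.09	0.76	6.22	1	Panax ginseng
mol26	Ginsenoside-Rh4_qt	ginsenoside rh4_qt	31.11	0.78	6.97	1	Panax ginseng
mol27	Malkangunin	malkangunin	57.71	0.63	4.09	1	Panax ginseng
mol28	Alexandrin_qt	alexandrin_qt	36.91	0.75	5.53	1	Panax ginseng
mol29	Ginsenoside rf	ginsenoside rf	17.74	0.24	4.66	5	Panax ginseng
mol30	Hederagenin	hederagenin	36.91	0.75	5.35	6	Astragalus membranaceus
mol31	Isorhamnetin	isorhamnetin	49.60	0.31	14.34	10	Astragalus membranaceus;Pulsatilla chinensis
mol32	7-O-methylisomucronulatol	7-o-methylisomucronulatol	74.69	0.30	2.98	11	Astragalus membranaceus
mol33	Rutin	rutin	3.20	0.68	6.22	15	Astragalus membranaceus
mol34	1,7-Dihydroxy-3,9-dimethoxy pterocarpene	1,7-dihydroxy-3,9-dimethoxy pterocarpene	39.05	0.48	7.95	5	Astragalus membranaceus
mol35	Isoferulic acid	isoferulic acid	50.83	0.06	2.45	7	Astragalus membranaceus
mol36	Betulinic acid	betulinic acid	55.38	0.78	8.87	1	Pulsatilla chinensis
mol37	Oleanolic acid	oleanolic acid	29.02	0.76	5.56	6	Pulsatilla chinensis
mol38	Sitosteryl acetate	sitosteryl acetate	40.39	0.85	6.34	1	Pulsatilla chinensis
mol39	Lanosterol	lanosterol	42.12	0.75	5.84	1	Pulsatilla chinensis
mol40	3-beta,23-Dihydroxy-lup-20(29)-ene-28-O-alpha-L-rhamnopyranosyl-(1-4)-beta-D-glucopyranosyl(1-6)-beta-D-glucopyranoside_qt	lupane triterpenoid glycoside_qt	37.59	0.79	6.70	1	Pulsatilla chinensis
mol41	Ursolic acid	ursolic acid	16.77	0.75	5.28	35	Pulsatilla chinensis
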