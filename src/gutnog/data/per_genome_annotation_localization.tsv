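genome_id	habitat_label	pse	sec	cyto	mem	total	eggnog	eggnog_pct
Anaerotruncus colihominis DSM 17241	gut	304	111	3496	516	4427	2214	50.0
Blautia hansenii DSM 20583	gut	292	80	2326	473	3171	2029	64.0
Butyrivibrio crossotus DSM 2876	gut	291	92	1803	343	2529	1669	66.0
Catenibacterium mitsuokai DSM 15897	gut	211	69	2311	386	2977	1799	60.4
Clostridium bartlettii DSM 16795	gut	245	88	2025	429	2787	2001	71.8
Clostridium bolteae ATCC BAA 613	gut	644	188	5386	1066	7284	3473	47.7
Clostridium leptum DSM 753	gut	293	91	3055	484	3923	1930	49.2
Clostridium nexile DSM 1787	gut	423	85	3152	579	4239	2157	50.9
Coprococcus comes ATCC 27758	gut	303	69	2954	587	3913	2055	52.5
Coprococcus eutactus ATCC 27759	gut	320	84	2166	412	2982	1859	62.3
Dorea formicigenerans ATCC 27755	gut	301	65	2438	473	3277	2072	63.2
Dorea longicatena DSM 13814	gut	248	53	2234	435	2970	1930	65.0
Eubacterium siraeum 70/3	gut	252	85	1702	308	2347	1486	63.3
Eubacterium ventriosum ATCC 27560	gut	255	168	1953	426	2802	1721	61.4
Faecalibacterium prausnitzii A2-165	gut	250	118	2644	463	3475	1849	53.2
Holdemania filiformis DSM 12042	gut	416	110	3075	622	4223	2167	51.3
Megamonas rupellensis DSM 19944	gut	137	130	1597	361	2225	1729	77.7
Mitsuokella multacida DSM 20544	gut	162	145	1885	366	2558	1768	69.1
Roseburia intestinalis M50/1	gut	327	114	2547	490	3478	2149	61.8
Ruminococcus gnavus ATCC 29149	gut	339	73	2958	543	3913	2266	57.9
Ruminococcus obeum A2-162	gut	279	177	2255	444	3155	2015	63.9
Ruminococcus torques L2-14	gut	248	55	2108	387	2798	1902	68.0
Subdoligranulum variabile DSM 15176	gut	319	90	2487	485	3381	2013	59.5
Acetivibrio cellulolyticus CD2	non_gut	591	435	3313	609	4948	2882	58.2
Acetobacterium woodii DSM 1030	non_gut	329	84	2611	449	3474	2424	69.8
Alkaliphilus metalliredigens QYMF	non_gut	506	113	3284	722	4625	3154	68.2
Alkaliphilus oremlandii OhILAs	non_gut	327	102	1972	435	2836	2250	79.3
Bacillus subtilis subtilis 168	non_gut	324	210	2867	775	4177	3035	72.7
Brevibacillus brevis NBRC 100599	non_gut	585	333	4139	890	5947	3932	66.1
Caldicellulosiruptor lactoaceticus DSM 9545	non_gut	194	144	1692	288	2319	1807	77.9
Caloramator australicus KCTC 5601	non_gut	205	87	2051	382	2725	1991	73.1
Clostridium acetobutylicum ATCC 824	non_gut	399	194	2702	552	3847	2790	72.5
Clostridium beijerinckii NCIMB 8052	non_gut	496	228	3594	702	5021	3416	68.0
Clostridium botulinum A str ATCC 3502	non_gut	319	128	2561	582	3591	2622	73.0
Clostridium cellulovorans ATCC 35296	non_gut	459	254	2995	546	4255	2882	67.7
Clostridium kluyveri NBRC 12016	non_gut	358	94	2572	499	3523	2584	73.3
Clostridium lentocellum DSM 5427	non_gut	473	204	2887	618	4183	2792	66.7
Clostridium phytofermentans ISDg	non_gut	538	141	2628	595	3903	2833	72.6
Ethanoligenens harbinense DSM 18485	non_gut	243	94	1983	381	2702	1963	72.6
Lactobacillus buchneri ATCC 11577	non_gut	183	172	2118	529	3002	1886	62.8
Lactobacillus delbrueckii bulgaricus ATCC 11842	non_gut	116	70	1099	244	1530	1125	73.5
Oenococcus oeni ATCC BAA 1163	non_gut	83	64	986	265	1675	1130	67.5
Pediococcus pentosaceus ATCC 25745	non_gut	134	42	1282	297	1755	1418	80.8
Solibacillus silvestris StLB046	non_gut	402	132	2621	668	3823	2705	70.8
Sulfobacillus acidophilus DSM 10332	non_gut	258	108	2522	583	3471	2172	62.6
Thermosinus carboxydivorans Nor1	non_gut	194	144	2006	406	2750	2087	75.9
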