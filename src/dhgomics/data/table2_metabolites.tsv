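id	rt	name	mz	adduct	formula	hmdb_id	kegg_id	trend
M1	0.86	L-Glutamine	145.0606	[M-H]-	C5H10N2O3	HMDB0000641	C00064	Down
M2	0.87	L-Threonine	120.0656	[M+H]+	C4H9NO3	HMDB0000167	C00188	Down
M3	0.9	L-Valine	118.0863	[M+H]+	C5H11NO2	HMDB0000883	C00183	Down
M4	0.93	Cytidine	242.0793	[M-H]-	C9H13N3O5	HMDB0000089	C00475	Down
M5	0.95	Hypoxanthine	137.0459	[M+H]+	C5H4N4O	HMDB0000157	C00262	Up
M6	0.95	Uric acid	169.0357	[M+H]+	C5H4N4O3	HMDB0000289	C00366	Up
M7	1.74	L-Tyrosine	180.0656	[M-H]-	C9H11NO3	HMDB0000158	C00082	Up
M8	1.86	L-Leucine	132.102	[M+H]+	C6H13NO2	HMDB0000687	C00123	Down
M9	3.52	L-Tryptophan	203.0818	[M-H]-	C11H12N2O2	HMDB0000929	C00078	Down
M10	3.96	Indole	118.0652	[M+H]+	C8H7N	HMDB0000738	C00463	Up
M11	4.03	Phenylacetylglutamine	263.1036	[M-H]-	C13H16N2O4	HMDB0006344	C04148	Down
M12	4.22	Protoporphyrinogen IX	569.3142	[M+H]+	C34H40N4O4	HMDB0001097	C01079	Up
M13	4.29	Coproporphyrin III	653.2657	[M-H]-	C36H38N4O8	HMDB0000570	C05770	Up
M14	4.38	Phenylalanylphenylalanine	313.1546	[M+H]+	C18H20N2O3	HMDB0013302		Up
M15	4.52	PE(18:4(6Z,9Z,12Z,15Z)/22:6(4Z,7Z,10Z,13Z,16Z,19Z))	784.4883	[M+H]+	C45H70NO8P	HMDB0009210		Up
M16	4.58	3,4-Dihydroxymandelic acid	183.0288	[M-H]-	C8H8O5	HMDB0001866	C05580	Up
M17	4.8	Indoleacrylic acid	188.0707	[M+H]+	C11H9NO2	HMDB0000734		Up
M18	5.08	Corticosterone	347.2215	[M+H]+	C21H30O4	HMDB0001547	C02140	Up
M19	5.56	Taurocholate	516.2989	[M+H]+	C26H45NO7S	HMDB0000036	C05122	Down
M20	5.64	Galactosylglycerol	253.093	[M-H]-	C9H18O8	HMDB0006790	C05401	Down
M21	5.96	Bilirubin	585.2705	[M+H]+	C33H36N4O6	HMDB0000054	C00486	Down
M22	6.08	Glycocholic acid	466.3163	[M+H]+	C26H43NO6	HMDB0000138	C01921	Down
M23	6.44	Taurochenodeoxycholic acid	498.289	[M-H]-	C26H45NO6S	HMDB0000951	C05465	Down
M24	6.66	LysoPA(0:0/18:2(9Z,12Z))	433.2356	[M-H]-	C21H39O7P	HMDB0007852		Down
M25	6.83	Dodecanoylcarnitine	344.2794	[M+H]+	C19H37NO4	HMDB0002250		Up
M26	6.88	Cholic acid	407.2796	[M-H]-	C24H40O5	HMDB0000619	C00695	Up
M27	6.89	Biliverdin	583.2547	[M+H]+	C33H34N4O6	HMDB0001008	C00500	Up
M28	7.15	Deoxycholylglycine	450.3213	[M+H]+	C26H43NO5	HMDB0242414		Down
M29	7.28	N-Succinyl-L,L-2,6-diaminopimelate	289.1054	[M-H]-	C11H18N2O7	HMDB0012267	C04421	Down
M30	7.28	13-Oxo-9,11-tridecadienoic acid	223.1333	[M-H]-	C13H20O3	HMDB0034564		Down
M31	7.45	Deoxycholic acid	391.2849	[M-H]-	C24H40O4	HMDB0000626	C04483	Down
M32	8.06	LysoPC(20:5(5Z,8Z,11Z,14Z,17Z)/0:0)	542.3217	[M+H]+	C28H48NO7P	HMDB0010397	C04230	Down
M33	8.1	PE(22:4(7Z,10Z,13Z,16Z)/22:5(4Z,7Z,10Z,13Z,16Z))	840.5488	[M-H]-	C49H80NO8P	HMDB0009603	C00350	Down
M34	8.12	Tetracosahexaenoic acid	357.2787	[M+H]+	C24H36O2	HMDB0002007		Down
M35	8.24	Palmitoylcarnitine	400.342	[M+H]+	C23H45NO4	HMDB0000222	C02990	Up
M36	8.32	4-Hydroxyphenylpyruvic acid	181.0497	[M+H]+	C9H8O4	HMDB0000707	C01179	Down
M37	8.36	LysoPC(P-18:1(9Z)/0:0)	506.3601	[M+H]+	C26H52NO6P	HMDB0010408	C04230	Down
M38	8.62	LysoPC(18:3(6Z,9Z,12Z)/0:0)	518.3218	[M+H]+	C26H48NO7P	HMDB0010387	C04230	Down
M39	8.78	Prostaglandin E2	353.2298	[M+H]+	C20H32O5	HMDB0001220	C00584	Up
M40	9.28	Androsterone glucuronide	467.2619	[M+H]+	C25H38O8	HMDB0002829	C11135	Down
M41	10.1	LysoPC(P-18:0/0:0)	508.3763	[M+H]+	C26H54NO6P	HMDB0013122	C04230	Down
M42	10.38	DG(16:0/LTE4/0:0)	752.5199	[M+H]+	C42H73NO8S	HMDB0295467		Down
M43	10.53	16-Hydroxyhexadecanoic acid	271.2277	[M-H]-	C16H32O3	HMDB0006294	C18218	Down
M44	10.66	PE(PGF1alpha/18:0)	820.5769	[M+H]+	C43H82NO11P	HMDB0261187		Down
M45	10.67	17-beta-Estradiol-3-glucuronide	447.1998	[M-H]-	C24H32O8	HMDB0006224	C05503	Up
M46	10.74	(9S,10S)-10-hydroxy-9-(phosphonooxy)octadecanoate	395.2199	[M-H]-	C18H37O7P	HMDB0059632	C15989	Down
M47	10.75	Docosahexaenoic acid	327.2328	[M-H]-	C22H32O2	HMDB0002183	C06429	Down
M48	10.97	Arachidonic acid	303.2327	[M-H]-	C20H32O2	HMDB0001043	C00219	Down
M49	11.17	Linoleic acid	279.2326	[M-H]-	C18H32O2	HMDB0000673	C01595	Down
M50	11.21	PC(14:0/18:2(9Z,12Z))	730.5375	[M+H]+	C40H76NO8P	HMDB0007874	C00157	Up
M51	11.43	Docosapentaenoic acid (22n-3)	329.2483	[M-H]-	C22H34O2	HMDB0006528	C16513	Down
M52	12.12	PC(22:6(4Z,7Z,10Z,13Z,16Z,19Z)/20:3(5Z,8Z,11Z))	856.5799	[M+H]+	C50H82NO8P	HMDB0008737	C00157	Down
M53	12.14	PC(18:2(9Z,12Z)/22:6(4Z,7Z,10Z,13Z,16Z,19Z))	830.5686	[M+H]+	C48H80NO8P	HMDB0008156	C00157	Down
M54	12.6	PE(20:4(5Z,8Z,11Z,14Z)/P-18:1(11Z))	748.5267	[M-H]-	C43H76NO7P	HMDB0009413	C00350	Up
M55	14.65	PC(18:0/20:4(8Z,11Z,14Z,17Z))	810.5997	[M+H]+	C46H84NO8P	HMDB0008049	C00157	Down
M56	14.72	PC(18:0/18:2(9Z,12Z))	786.5998	[M+H]+	C44H84NO8P	HMDB0008039	C00157	Down
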