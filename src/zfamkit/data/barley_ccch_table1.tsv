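gene_name	gene_id	chromosome	length_aa	isoelectric_point	molecular_weight_kda	subcellular_location	gravy	est_hits
HvC3H1	HORVU.MOREX.r2.1HG0011690	chr1H	609	8.16	64.492	Nucleus	-0.324	109
HvC3H2	HORVU.MOREX.r2.1HG0067940	chr1H	278	5.45	29.946	Nucleus	-0.375	60
HvC3H3	HORVU.MOREX.r2.1HG0072390	chr1H	304	9.15	34.276	Nucleus	-1.163	11
HvC3H4	HORVU.MOREX.r2.1HG0074950	chr1H	402	9.57	42.999	Nucleus	-0.305	2
HvC3H5	HORVU.MOREX.r2.1HG0074970	chr1H	327	9.42	35.232	Nucleus	-0.389	6
HvC3H6	HORVU.MOREX.r2.1HG0078680	chr1H	1456	5.13	160.373	Nucleus	-0.841	4
HvC3H7	HORVU.MOREX.r2.2HG0082780	chr2H	914	5.48	98.863	Nucleus	-0.561	0
HvC3H8	HORVU.MOREX.r2.2HG0091490	chr2H	697	6.26	73.624	Chloroplast	-0.384	25
HvC3H9	HORVU.MOREX.r2.2HG0110160	chr2H	668	6.33	71.328	Nucleus	-0.468	48
HvC3H10	HORVU.MOREX.r2.2HG0140180	chr2H	341	10.15	38.974	Nucleus	-1.009	22
HvC3H11	HORVU.MOREX.r2.2HG0166340	chr2H	304	9.38	31.487	Nucleus	-0.623	33
HvC3H12	HORVU.MOREX.r2.2HG0176080	chr2H	695	5.49	77.804	Nucleus	-1.149	11
HvC3H13	HORVU.MOREX.r2.3HG0196310	chr3H	379	7.51	40.767	Nucleus	-0.535	7
HvC3H14	HORVU.MOREX.r2.3HG0200320	chr3H	224	9.13	24.591	Nucleus	-0.81	0
HvC3H15	HORVU.MOREX.r2.3HG0200330	chr3H	232	6.17	24.956	Nucleus	-0.616	1
HvC3H16	HORVU.MOREX.r2.3HG0209640	chr3H	165	8.88	18.115	Extracellular	-0.54	0
HvC3H17	HORVU.MOREX.r2.3HG0210630	chr3H	1008	6.58	113.677	Nucleus	-0.151	0
HvC3H18	HORVU.MOREX.r2.3HG0210880	chr3H	467	7.85	49.838	Nucleus	-0.493	53
HvC3H19	HORVU.MOREX.r2.3HG0210900	chr3H	426	8.07	45.402	Nucleus	-0.658	16
HvC3H20	HORVU.MOREX.r2.3HG0221360	chr3H	676	5.58	73.029	Nucleus	-0.599	0
HvC3H21	HORVU.MOREX.r2.3HG0225190	chr3H	500	8.67	54.722	Nucleus	-0.648	32
HvC3H22	HORVU.MOREX.r2.3HG0228250	chr3H	384	8.6	42.042	Nucleus	-0.419	9
HvC3H23	HORVU.MOREX.r2.3HG0230880	chr3H	281	9.59	32.735	Chloroplast Nucleus	-1.177	64
HvC3H24	HORVU.MOREX.r2.3HG0253280	chr3H	370	5.21	42.08	Nucleus	-1.102	0
HvC3H25	HORVU.MOREX.r2.3HG0258540	chr3H	435	8.82	47.4	Nucleus	-0.564	61
HvC3H26	HORVU.MOREX.r2.4HG0279920	chr4H	750	7.59	80.177	Nucleus	-0.407	61
HvC3H27	HORVU.MOREX.r2.4HG0294950	chr4H	613	6.04	65.557	Nucleus	-0.418	0
HvC3H28	HORVU.MOREX.r2.4HG0318770	chr4H	299	8.3	32.522	Nucleus	-0.595	2
HvC3H29	HORVU.MOREX.r2.4HG0325540	chr4H	326	7.14	36.231	Nucleus	-1.003	11
HvC3H30	HORVU.MOREX.r2.5HG0362710	chr5H	691	9.39	78.976	Nucleus	-1.218	5
HvC3H31	HORVU.MOREX.r2.5HG0370720	chr5H	617	5.82	65.496	Nucleus	-0.292	74
HvC3H32	HORVU.MOREX.r2.5HG0374920	chr5H	509	6.39	55.923	Nucleus	-0.702	23
HvC3H33	HORVU.MOREX.r2.5HG0377520	chr5H	442	8.78	47.516	Nucleus	-0.504	20
HvC3H34	HORVU.MOREX.r2.5HG0383720	chr5H	598	5.86	64.404	Nucleus	-0.418	0
HvC3H35	HORVU.MOREX.r2.5HG0394250	chr5H	127	8.89	14.407	Nucleus	-0.997	0
HvC3H36	HORVU.MOREX.r2.5HG0407060	chr5H	314	9.25	36.792	Chloroplast Nucleus	-1.241	36
HvC3H37	HORVU.MOREX.r2.5HG0429150	chr5H	752	7.39	85.417	Nucleus	-1.256	5
HvC3H38	HORVU.MOREX.r2.5HG0439140	chr5H	404	8.81	46.699	Nucleus	-1.655	0
HvC3H39	HORVU.MOREX.r2.6HG0469460	chr6H	337	5.82	36.132	Nucleus	-0.461	0
HvC3H40	HORVU.MOREX.r2.6HG0475520	chr6H	211	9.17	23.087	Nucleus	-0.813	0
HvC3H41	HORVU.MOREX.r2.6HG0475530	chr6H	342	8.03	36.041	Nucleus	-0.357	0
HvC3H42	HORVU.MOREX.r2.6HG0475540	chr6H	358	8.63	38.145	Chloroplast	-0.34	0
HvC3H43	HORVU.MOREX.r2.6HG0475570	chr6H	308	9.49	31.997	Chloroplast	-0.541	39
HvC3H44	HORVU.MOREX.r2.6HG0500510	chr6H	433	7.88	46.635	Extracellular	-0.222	0
HvC3H45	HORVU.MOREX.r2.6HG0505660	chr6H	359	6.66	40.211	Nucleus	-0.467	5
HvC3H46	HORVU.MOREX.r2.6HG0515160	chr6H	1001	8.81	110.273	Nucleus	-1.121	16
HvC3H47	HORVU.MOREX.r2.6HG0526270	chr6H	647	5.23	71.397	Nucleus	-1.069	45
HvC3H48	HORVU.MOREX.r2.7HG0560290	chr7H	489	9.46	55.275	Nucleus	-0.795	9
HvC3H49	HORVU.MOREX.r2.7HG0579580	chr7H	363	6.85	38.791	Nucleus	-0.706	20
HvC3H50	HORVU.MOREX.r2.7HG0600900	chr7H	297	9.64	30.833	Chloroplast Nucleus	-0.541	46
HvC3H51	HORVU.MOREX.r2.7HG0602740	chr7H	407	8.56	44.684	Nucleus	-0.954	26
HvC3H52	HORVU.MOREX.r2.7HG0607870	chr7H	375	9.32	42.524	Nucleus	-1.372	6
HvC3H53	HORVU.MOREX.r2.7HG0609970	chr7H	648	6.27	71.01	Nucleus	-0.962	100
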