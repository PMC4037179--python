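index	rt_label	rt_sort	name	chemical_class	healthy_mean	healthy_sd	mdd_mean	mdd_sd	els_mean	els_sd	nonels_mean	nonels_sd	vip_a	vip_b	vip_c	vip_d
1	6.116	6.116	Lactic acid	organic acid	1.6345	0.41723	1.9009	0.47168	1.7224	0.48594	2.0795	0.39025			1.23	1.17
2	7.033	7.033	Alanine	amino acid	0.4348	0.07446	0.5018	0.13743	0.4365	0.09907	0.5672	0.14104	1.31	1.25	1.33	1.45
3	7.933	7.933	Oxalic acid	organic acid	0.608	0.12699	0.6842	0.21615	0.6589	0.08991	0.7096	0.29350
4	8.399	8.399	Hydroxybutyric acid	organic acid	0.1686	0.16895	0.1484	0.168	0.1417	0.014071	0.1570	0.20161
5	9.75	9.75	Valine	amino acid	0.4496	0.06243	0.4517	0.1094	0.4410	0.06865	0.4624	0.13973
6	10.866	10.866	Urea	other	3.1162	0.96887	3.0487	0.90941	2.9548	0.66486	3.1425	1.10959
7	11.316	11.316	Phosphoric acid	mineral acid	3.4182	0.8181	3.6007	0.98405	3.1813	0.27462	4.0201	1.23997				1.3
8	11.75	11.75	Leucine	amino acid	0.17	0.04885	0.1661	0.0631	0.1535	0.04123	0.1805	0.08014	1.03	1.01
9	11.82	11.82	Proline	amino acid	0.1108	0.07821	0.1788	0.1161	0.1359	0.07335	0.2162	0.1339	1.05		1.1	1.05
10	12.05	12.05	Glycine	amino acid	0.3351	0.07559	0.4490	0.1344	0.3990	0.07520	0.4990	0.16146	1.38	1.55	1.39	1.16
11	12.333	12.333	Butanedioic acid	organic acid	0.0239	0.00882	0.0434	0.04028	0.0269	0.00782	0.0625	0.05293	1.03		1.24	1.36
12	12.377	12.377	Glyceric acid	organic acid	0.0204	0.01170	0.0214	0.01203	0.0162	0.00702	0.0285	0.01394				1.5
13	13.5	13.5	Serine	amino acid	0.1421	0.09798	0.2032	0.10309	0.1944	0.07278	0.2128	0.12977	1.01	1.13
14	14.15	14.15	Threonine	amino acid	0.1622	0.10725	0.2205	0.11248	0.2144	0.08284	0.2269	0.13870		1.15
15	16.233+17.767	16.233	Aspartic acid	amino acid	0.9201	0.32851	1.1121	0.36793	1.1571	0.19671	1.0567	0.50531		1.56
16	17.434	17.434	Pyroglutamate	amino acid	0.1631	0.09368	0.1895	0.09589	0.1762	0.07038	0.2064	0.12116
17	18.55	18.55	Erythronic acid	organic acid	0.0260	0.02118	0.0168	0.00821	0.0169	0.00920	0.0167	0.007	1.09	1.05
18	23.951	23.951	Mannose	carbohydrate	0.0482	0.02763	0.0355	0.02175	0.0307	0.02069	0.0414	0.2214	1.02	1.37
19	24.234	24.234	Isocitric acid	organic acid	0.3288	0.13325	0.3388	0.10913	0.3373	0.05798	0.3410	0.15705
20	24.867	24.867	Arabopyranose	carbohydrate	0.8943	0.15508	0.9838	0.24707	0.9478	0.20382	1.0197	0.28393
21	25.734	25.734	Unknown carbohydrate	carbohydrate	1.6946	0.63606	1.8667	0.58277	1.7689	0.32809	2.0119	0.73246
22	25.851	25.851	Glucose	carbohydrate	3.7220	0.64182	4.2806	0.97574	3.9382	0.85764	4.6231	0.98319			1.21	1.08
23	26.201	26.201	Galactose	carbohydrate	1.5240	0.17550	1.7945	0.34136	1.6611	0.32737	1.9278	0.30658	1.32	1		1.19
24	26.434	26.434	Sorbitol	carbohydrate	0.0175	0.0335	0.3028	0.63857	0.4385	0.819	0.1254	0.1759	1.09	1.44	1.1
25	27.001	27.001	Gluconate	organic acid	0.0805	0.04228	0.072	0.03247	0.0757	0.03107	0.0673	0.03449
26	27.567	27.567	Glucopyranose	carbohydrate	2.5494	0.42851	2.7061	0.59253	2.3710	0.40559	3.0413	0.56461			1.16	1.76
27	28.468	28.468	6-deoxy-mannopyrannose	carbohydrate	0.1005	0.05662	0.1401	0.08907	0.1382	0.05129	0.1421	0.11898		1.31
28	28.784	28.784	Palmitic acid	fatty acid	0.7542	0.19656	0.6426	0.19054	0.6827	0.17838	0.6024	0.19766
29	29.534	29.534	Myoinositol	carbohydrate	0.1330	0.05742	0.1041	0.05806	0.0989	0.02892	0.1098	0.07914	1.1	1.4
30	30.601	30.601	Heptadecylic acid	fatty acid	0.0169	0.00972	0.012	0.00565	0.0123	0.00544	0.0115	0.00641	1.21	1.15
31	31.484	31.484	Tryptophane	amino acid	0.02	0.01	0.0232	0.01423	0.02	0.012	0.03	0.018
32	31.751	31.751	Linoleic acid	fatty acid	0.1394	0.06166	0.0689	0.05385	0.0914	0.05650	0.0344	0.02334	1.63	1.49	1.75	1.53
33	31.868	31.868	Oleic acid	fatty acid	0.1874	0.09155	0.1102	0.0869	0.1292	0.07510	0.0836	0.09759	1.3	1.3	1.21
34	32.384	32.384	Stearic acid	fatty acid	0.8864	0.18828	0.7775	0.2	0.8424	0.15551	0.7096	0.22150			1.01	1.01
35	45.652	45.652	Cholesterol	sterol	2.0814	0.4245	1.1613	0.91029	1.7824	0.66708	0.4711	0.58983	1.6	1.03	2.18	2.23
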