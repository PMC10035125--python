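# Synthetic trinucleotide physicochemical property table (stand-in).
# 12 properties x 64 trinucleotides. Property names follow the conventional
# trinucleotide descriptor set; 'Trinucleotide GC content' and the molecular
# weights are computed from the word, the remaining values are deterministic
# pseudo-random placeholders, NOT measured constants. Supply your own TSV
# (same layout) to use published values.
property	AAA	AAC	AAG	AAT	ACA	ACC	ACG	ACT	AGA	AGC	AGG	AGT	ATA	ATC	ATG	ATT	CAA	CAC	CAG	CAT	CCA	CCC	CCG	CCT	CGA	CGC	CGG	CGT	CTA	CTC	CTG	CTT	GAA	GAC	GAG	GAT	GCA	GCC	GCG	GCT	GGA	GGC	GGG	GGT	GTA	GTC	GTG	GTT	TAA	TAC	TAG	TAT	TCA	TCC	TCG	TCT	TGA	TGC	TGG	TGT	TTA	TTC	TTG	TTT
Bendability (DNase)	0.0366	-0.2101	-0.1877	-0.4684	-0.2495	-0.5073	-0.1018	-0.3254	-0.3985	-0.3693	-0.3103	-0.1081	-0.2176	-0.4207	-0.4402	-0.4689	-0.1424	-0.1989	-0.4842	-0.5766	-0.2968	-0.3898	-0.1929	-0.309	-0.221	-0.1438	-0.1017	-0.3272	-0.1611	-0.3914	-0.505	-0.2496	-0.0756	-0.0368	-0.302	-0.5985	-0.2336	-0.3297	-0.1806	-0.1005	-0.3702	-0.4195	-0.3624	-0.4148	-0.4708	-0.2554	-0.425	-0.3447	-0.3538	-0.4037	-0.1876	-0.3778	-0.3107	-0.1543	-0.3221	-0.5553	-0.381	-0.3813	-0.1854	-0.0026	-0.2623	-0.3214	-0.0386	-0.4214
Bendability (consensus)	0.4074	0.2603	0.6544	2.1046	1.08	-0.183	0.773	1.5035	2.3894	1.3333	0.6709	1.9576	1.4205	0.6178	-0.2574	0.5527	1.4868	-0.6972	-1.2694	1.0124	-1.2013	-0.9497	0.2316	0.1941	0.5099	0.626	1.0164	0.3332	-0.452	-2.615	1.7793	1.2845	1.1066	0.4049	-0.5247	0.9435	0.3471	-1.0459	1.5295	-1.1171	-0.0489	2.319	-0.4584	0.6076	1.5558	0.4167	-1.1127	-0.125	0.3522	-1.2167	1.9502	0.7453	1.1674	0.686	0.806	0.0071	-1.1985	1.1179	0.4281	2.0841	-0.8673	0.563	2.7402	-1.0641
Consensus rigid	23.0095	-15.5481	1.1299	-2.1468	-7.1719	-3.1061	16.5859	2.0758	-17.3777	-8.0541	1.4512	-18.5922	-9.1239	-5.295	-28.0233	24.8871	-21.5498	0.8891	-2.2803	-8.0478	16.2578	0.8611	-11.1523	15.7038	7.407	-13.8543	-20.4174	11.8605	-1.822	-19.5664	7.3825	-19.2438	-9.2474	-10.9702	-26.533	9.2398	47.0352	8.6621	5.5273	-3.3707	-0.8316	3.8225	8.4848	-6.6028	0.7364	-2.6316	7.7715	12.9569	15.1488	-5.5191	-5.9624	9.8309	-2.858	-2.1825	6.9503	5.8996	18.6747	-15.4262	16.0356	-5.2943	10.099	-16.3466	-0.6683	-7.2321
Consensus roll	0.0901	-1.4643	-1.713	-0.5711	0.029	-0.8627	-0.3355	-0.624	-0.8579	0.2964	-0.8056	-0.1126	-1.7309	-0.9561	-0.051	-1.1699	-2.5133	-0.1998	-0.3358	-1.0265	-0.7078	-1.0622	-0.4849	0.0895	-0.5423	-0.861	-1.1762	-0.9156	-1.1898	-0.0129	-1.631	-1.2514	-0.5053	-0.5164	-0.5821	-1.1191	-0.6206	-1.9214	-1.9975	-1.8049	-0.4755	0.3147	-1.1202	-1.2213	-1.007	0.6757	-0.5967	-0.686	-1.2148	-0.3653	0.278	-0.6064	-1.4028	0.2903	-0.7746	0.6645	-1.5972	-0.8736	-0.5436	-2.154	-0.6803	-0.2679	-0.8585	-0.4069
DNase I	-0.1854	-5.8715	-4.1498	-5.8335	-0.5317	-4.8139	-4.834	-11.2564	-4.0881	0.8134	-11.0514	-1.612	-3.1913	-9.7155	-4.6452	0.6094	-3.0781	-1.6976	1.2138	-4.2834	0.2853	-7.827	-6.3499	2.5254	2.169	0.5672	-8.7786	-3.882	-6.4182	4.3472	-8.1653	-7.8801	-5.2742	-1.726	-5.2074	-4.1289	-1.8352	-2.8529	-10.1517	-7.7651	3.3002	-2.7701	4.0171	2.6451	1.3107	-2.6674	2.9681	-4.6374	5.6644	-0.6137	-0.5751	-4.3173	-4.9894	-3.7422	-4.755	-6.0863	-6.87	-1.9884	1.8309	4.7794	0.228	-3.086	-0.3164	3.8623
DNase I rigid	3.3201	2.8123	1.4084	3.9887	0.8846	0.5351	3.2442	4.5122	4.4169	4.2511	1.9381	2.287	4.8096	6.7007	-2.8611	4.9851	2.991	2.4335	1.0543	1.2619	0.1092	3.0642	0.5621	2.1447	-0.5124	4.9071	3.8722	0.1532	3.422	1.7016	0.7403	2.6312	4.1822	5.5246	3.0262	4.8427	3.8528	3.847	4.4559	-0.2588	1.6779	5.4916	-0.2255	0.7747	6.2692	0.4013	2.7074	2.9947	1.8595	4.3236	4.185	1.0282	5.9549	0.7717	1.5159	2.1208	2.8085	0.1634	2.8715	-2.0692	1.3537	0.5231	0.9029	2.1403
Nucleosome	-0.172	-0.5368	-0.2697	0.0403	-0.3452	-0.2563	-0.1885	0.0082	-0.0963	-0.2238	-0.4217	-0.1282	-0.8671	-0.0864	-0.3636	-0.0345	-0.2017	0.1316	-0.3386	-0.6555	-0.1821	-0.3038	-0.2112	0.0919	-0.4018	-0.0296	0.0205	0.0639	-0.66	-0.1536	-0.3522	-0.2438	-0.3811	-0.266	0.033	0.2161	-0.0241	-0.4786	0.1058	-0.4799	-0.2771	0.078	-0.3269	-0.0191	-0.2509	-0.4603	-0.1379	-0.3145	0.2272	0.2459	0.1825	-0.4275	0.2605	-0.1132	-0.067	-0.1402	-0.3153	-0.1554	0.0223	0.1801	-0.0511	-0.182	-0.2983	-0.2601
Nucleosome Rigid	1.1725	-1.4165	-1.5858	1.787	1.7243	2.3957	1.1275	-0.0518	-1.5135	-0.419	-2.3527	1.2622	1.5059	2.7557	-1.6788	-1.1096	1.6979	1.301	-1.9357	-0.1399	0.9747	0.3013	1.3565	0.8824	0.0584	1.3653	0.7255	2.4461	-1.1781	0.5087	-0.1127	0.4907	1.3927	1.7275	-2.1468	2.4418	1.58	1.5591	0.9275	2.1494	1.4046	-1.6714	-0.0971	0.476	0.3217	0.2026	1.6766	-0.7297	-0.2173	-0.5569	0.7853	1.4398	-0.4367	1.3683	0.0638	2.7898	-2.2991	0.8028	2.4248	0.312	-0.7198	-0.388	1.6002	0.0655
Nucleosome positioning	-8.8623	-7.1308	6.3301	14.3299	-12.4835	-18.0193	-17.8165	6.4289	26.3099	-8.1905	9.445	-6.3125	13.225	-22.2893	8.3659	-19.6546	-12.9124	4.5108	-3.9106	-1.3908	7.3824	2.5559	21.6375	10.8046	-12.9369	-1.3899	-8.4584	-6.31	25.9972	-11.8312	18.5169	21.955	40.0813	-0.1021	3.6035	4.2144	-5.5856	26.0417	28.8084	-34.1134	-4.9094	17.4475	-15.479	-10.4798	0.2283	-0.4547	-2.986	-2.3522	26.5604	-34.6756	-7.859	-17.2857	3.1813	-6.9529	6.7885	-0.2118	33.8835	-19.8944	-7.5312	12.6646	-6.0211	1.8895	-23.1555	10.2138
MW Daltons	939.63	915.6	955.63	930.62	915.6	891.57	931.6	906.59	955.63	931.6	971.63	946.62	930.62	906.59	946.62	921.61	915.6	891.57	931.6	906.59	891.57	867.54	907.57	882.56	931.6	907.57	947.6	922.59	906.59	882.56	922.59	897.58	955.63	931.6	971.63	946.62	931.6	907.57	947.6	922.59	971.63	947.6	987.63	962.62	946.62	922.59	962.62	937.61	930.62	906.59	946.62	921.61	906.59	882.56	922.59	897.58	946.62	922.59	962.62	937.61	921.61	897.58	937.61	912.6
MW-kg	1.56029e-24	1.52039e-24	1.58686e-24	1.54533e-24	1.52039e-24	1.48049e-24	1.54696e-24	1.50543e-24	1.58686e-24	1.54696e-24	1.61343e-24	1.5719e-24	1.54533e-24	1.50543e-24	1.5719e-24	1.53037e-24	1.52039e-24	1.48049e-24	1.54696e-24	1.50543e-24	1.48049e-24	1.44058e-24	1.50706e-24	1.46553e-24	1.54696e-24	1.50706e-24	1.57353e-24	1.532e-24	1.50543e-24	1.46553e-24	1.532e-24	1.49047e-24	1.58686e-24	1.54696e-24	1.61343e-24	1.5719e-24	1.54696e-24	1.50706e-24	1.57353e-24	1.532e-24	1.61343e-24	1.57353e-24	1.64e-24	1.59847e-24	1.5719e-24	1.532e-24	1.59847e-24	1.55694e-24	1.54533e-24	1.50543e-24	1.5719e-24	1.53037e-24	1.50543e-24	1.46553e-24	1.532e-24	1.49047e-24	1.5719e-24	1.532e-24	1.59847e-24	1.55694e-24	1.53037e-24	1.49047e-24	1.55694e-24	1.51541e-24
Trinucleotide GC content	0	0.333333	0.333333	0	0.333333	0.666667	0.666667	0.333333	0.333333	0.666667	0.666667	0.333333	0	0.333333	0.333333	0	0.333333	0.666667	0.666667	0.333333	0.666667	1	1	0.666667	0.666667	1	1	0.666667	0.333333	0.666667	0.666667	0.333333	0.333333	0.666667	0.666667	0.333333	0.666667	1	1	0.666667	0.666667	1	1	0.666667	0.333333	0.666667	0.666667	0.333333	0	0.333333	0.333333	0	0.333333	0.666667	0.666667	0.333333	0.333333	0.666667	0.666667	0.333333	0	0.333333	0.333333	0
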